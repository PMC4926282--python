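"""Synthetic LCFA-pulse study generator.

Produces complete, seeded datasets — scaffold coverage, scaffold-to-bin
assignments, gene annotations, experimental design, and reactor process
curves — with the derived structure of the real study baked in as
defaults: 106 genome bins of which 45 carry a planted pulse response
(groups A/B/C/D), two inocula (non-acclimatized and acclimatized to
LCFA), single oleate pulses of 2 and 3 g/L-reactor with two biological
replicates per treatment, three experimental periods, functional
categories over-represented in the positively responding bins, and
process trajectories with dose-dependent methane inhibition and an
acetate/propionate reversal.

Every draw comes from one seeded generator, so a fixed seed gives
byte-identical datasets. A truth manifest (true group labels, planted
enrichments, process template parameters) accompanies each dataset so
recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from binflux.io import CoverageMatrix, DESIGN_COLUMNS, PROCESS_COLUMNS, write_report

SETS = ("non_acclimatized", "acclimatized")
RESPONSE_GROUPS = ("A", "B", "C", "D")


@dataclass
class CommunitySpec:
    """Shape of the synthetic microbial community."""

    n_bins: int = 106
    n_responsive: int = 45
    group_proportions: dict[str, float] = field(
        default_factory=lambda: {"A": 0.25, "B": 0.25, "C": 0.25, "D": 0.25}
    )
    scaffolds_per_bin: tuple[int, int] = (5, 15)
    scaffold_length_meanlog: float = 8.5  # ~4900 bp median
    scaffold_length_sdlog: float = 0.8
    decoy_fraction: float = 0.10  # extra sub-500 bp scaffolds, removed by the filter
    genes_per_bin: tuple[int, int] = (120, 180)
    n_categories: int = 20
    planted_enrichment: list[tuple[str, tuple[str, ...], float]] = field(
        default_factory=lambda: [
            ("chemotaxis_like", ("A", "B"), 5.0),
            ("flagellar_like", ("A", "B"), 5.0),
        ]
    )
    multi_category_rate: float = 0.05  # genes carrying a second category
    response_fold: float = 4.0
    inoculum_fold: float = 2.0  # A/B enriched in acclimatized, D in non-acclimatized
    baseline_meanlog: float = 1.0
    baseline_sdlog: float = 0.8

    def validate(self) -> None:
        if not 0 <= self.n_responsive <= self.n_bins:
            raise ValueError("n_responsive must lie in [0, n_bins]")
        if abs(sum(self.group_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("group_proportions must sum to 1")
        if set(self.group_proportions) != set(RESPONSE_GROUPS):
            raise ValueError(f"group_proportions must cover {RESPONSE_GROUPS}")
        if self.response_fold <= 1:
            raise ValueError("response_fold must be > 1")


@dataclass
class DesignSpec:
    """Sampling layout of the two experimental sets."""

    doses: tuple[float, ...] = (2.0, 3.0)
    replicates: int = 2
    period_days: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"I": (1, 4), "II": (5, 14), "III": (15, 24)}
    )
    samples_per_period: int = 2
    aligned_reads_range: tuple[int, int] = (16_000_000, 20_000_000)
    noise_cv: float = 0.2

    def validate(self) -> None:
        if self.replicates < 1 or self.samples_per_period < 1:
            raise ValueError("replicates and samples_per_period must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")

    def sampling_days(self, period: str) -> list[int]:
        lo, hi = self.period_days[period]
        k = self.samples_per_period
        if hi - lo + 1 < k:
            raise ValueError(f"period {period} too short for {k} samples")
        return [int(round(x)) for x in np.linspace(lo, hi, k)]


@dataclass
class ProcessSpec:
    """Deterministic process-curve templates plus noise levels.

    Yields in mL CH4/gVS, concentrations in g/L. Inhibition depths are
    the fractional methane-yield drop at the nadir per (set, dose).
    """

    baseline_yield: float = 260.0
    recovered_yield: float = 265.0
    inhibition_depth: dict[tuple[str, float], float] = field(
        default_factory=lambda: {
            ("non_acclimatized", 3.0): 0.95,
            ("non_acclimatized", 2.0): 0.67,
            ("acclimatized", 3.0): 0.62,
            ("acclimatized", 2.0): 0.31,
        }
    )
    nadir_day: dict[tuple[str, float], int] = field(
        default_factory=lambda: {
            ("non_acclimatized", 3.0): 8,
            ("non_acclimatized", 2.0): 7,
            ("acclimatized", 3.0): 7,
            ("acclimatized", 2.0): 7,
        }
    )
    acpr_initial: dict[str, float] = field(
        default_factory=lambda: {"non_acclimatized": 6.0, "acclimatized": 4.7}
    )
    acpr_final: dict[tuple[str, float], float] = field(
        default_factory=lambda: {
            ("non_acclimatized", 2.0): 0.3,
            ("non_acclimatized", 3.0): 0.3,
            ("acclimatized", 2.0): 0.5,
            ("acclimatized", 3.0): 0.4,
        }
    )
    total_vfa: float = 2.5
    butyrate: float = 0.2
    ph: float = 7.8
    oscillation_tau_days: float = 3.0
    oscillation_omega: float = 1.2
    noise_sd_yield: float = 6.0
    noise_sd_vfa: float = 0.03
    noise_sd_ph: float = 0.05

    def validate(self) -> None:
        for key, depth in self.inhibition_depth.items():
            if not 0 < depth < 1:
                raise ValueError(f"inhibition depth for {key} must be in (0,1)")
        for key, r in {**self.acpr_final}.items():
            if r <= 0:
                raise ValueError(f"acpr_final for {key} must be > 0")


def _group_counts(spec: CommunitySpec) -> dict[str, int]:
    """Deterministic allocation of responsive bins to groups.

    Floors of the proportions, remainder distributed in A, B, C, D
    order.
    """
    counts = {g: int(spec.n_responsive * spec.group_proportions[g]) for g in RESPONSE_GROUPS}
    short = spec.n_responsive - sum(counts.values())
    for g in RESPONSE_GROUPS:
        if short <= 0:
            break
        counts[g] += 1
        short -= 1
    return counts


def generate_community(
    spec: CommunitySpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Draw bins, scaffolds and true response-group labels.

    Returns ``(bins, scaffolds, bin_map)`` where ``bins`` has columns
    ``bin_id, true_group, baseline_non_acclimatized,
    baseline_acclimatized, n_scaffolds``; ``scaffolds`` has
    ``scaffold_id, length_bp, bin_id, is_decoy``; and ``bin_map`` maps
    scaffold to bin for the analysis-grade (non-decoy) scaffolds and
    decoys alike (the length filter, not the map, removes decoys).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    counts = _group_counts(spec)
    labels = []
    for g in RESPONSE_GROUPS:
        labels.extend([g] * counts[g])
    labels.extend(["NONE"] * (spec.n_bins - spec.n_responsive))

    width = len(str(spec.n_bins))
    bin_ids = [f"GB{str(i + 1).zfill(width)}" for i in range(spec.n_bins)]
    # shuffle which bin gets which label, deterministically
    perm = rng.permutation(spec.n_bins)
    true_group = {bin_ids[i]: labels[int(perm[i])] for i in range(spec.n_bins)}

    base = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, spec.n_bins)
    base_by_set = {s: base.copy() for s in SETS}
    for i, b in enumerate(bin_ids):
        g = true_group[b]
        if g in ("A", "B"):
            base_by_set["acclimatized"][i] *= spec.inoculum_fold
        elif g == "D":
            base_by_set["non_acclimatized"][i] *= spec.inoculum_fold

    scaff_rows = []
    for i, b in enumerate(bin_ids):
        n_scaff = int(rng.integers(spec.scaffolds_per_bin[0], spec.scaffolds_per_bin[1] + 1))
        lengths = rng.lognormal(
            spec.scaffold_length_meanlog, spec.scaffold_length_sdlog, n_scaff
        )
        lengths = np.maximum(lengths.astype(int), 501)
        for j, L in enumerate(lengths):
            scaff_rows.append(
                {"scaffold_id": f"{b}_s{j + 1}", "length_bp": int(L),
                 "bin_id": b, "is_decoy": False}
            )
        n_decoy = int(np.ceil(n_scaff * spec.decoy_fraction))
        decoy_lengths = rng.integers(100, 501, n_decoy)  # <= 500 bp, filtered out
        for j, L in enumerate(decoy_lengths):
            scaff_rows.append(
                {"scaffold_id": f"{b}_d{j + 1}", "length_bp": int(L),
                 "bin_id": b, "is_decoy": True}
            )
    scaffolds = pd.DataFrame(scaff_rows)
    bins = pd.DataFrame(
        {
            "bin_id": bin_ids,
            "true_group": [true_group[b] for b in bin_ids],
            "baseline_non_acclimatized": base_by_set["non_acclimatized"],
            "baseline_acclimatized": base_by_set["acclimatized"],
            "n_scaffolds": scaffolds.loc[~scaffolds["is_decoy"]]
            .groupby("bin_id")
            .size()
            .reindex(bin_ids)
            .to_numpy(),
        }
    )
    bin_map = dict(zip(scaffolds["scaffold_id"], scaffolds["bin_id"]))
    return bins, scaffolds, bin_map


def build_design(design: DesignSpec, seed: int) -> pd.DataFrame:
    """Sample sheet for both experimental sets.

    Reactor ids are ``R<set-prefix><dose>g<replicate>``; each reactor is
    sampled ``samples_per_period`` times per period; aligned-read counts
    are drawn uniformly from ``aligned_reads_range``.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    rows = []
    for eset in SETS:
        prefix = "N" if eset == "non_acclimatized" else "A"
        for dose in design.doses:
            for rep in range(1, design.replicates + 1):
                reactor = f"R{prefix}{int(dose)}g{rep}"
                for period in ("I", "II", "III"):
                    for day in design.sampling_days(period):
                        rows.append(
                            {
                                "sample_id": f"{reactor}_d{day:02d}",
                                "experimental_set": eset,
                                "reactor_id": reactor,
                                "replicate": rep,
                                "lcfa_dose": float(dose),
                                "period": period,
                                "day": int(day),
                                "aligned_reads": int(
                                    rng.integers(*design.aligned_reads_range)
                                ),
                            }
                        )
    return pd.DataFrame(rows, columns=DESIGN_COLUMNS)


def simulate_trajectories(
    bins: pd.DataFrame, design_table: pd.DataFrame, spec: CommunitySpec
) -> pd.DataFrame:
    """True (noise-free) abundance of every bin in every sample.

    Group A: baseline x fold in period II only; B: fold in II and III;
    C: 1/fold in III only; D: 1/fold in II and III; NONE: flat. The
    per-set baselines already carry the inoculum enrichment (A/B bins
    higher in the acclimatized set, D bins in the non-acclimatized).
    """
    fold = spec.response_fold
    mult = {
        "A": {"I": 1.0, "II": fold, "III": 1.0},
        "B": {"I": 1.0, "II": fold, "III": fold},
        "C": {"I": 1.0, "II": 1.0, "III": 1.0 / fold},
        "D": {"I": 1.0, "II": 1.0 / fold, "III": 1.0 / fold},
        "NONE": {"I": 1.0, "II": 1.0, "III": 1.0},
    }
    base_cols = {
        "non_acclimatized": bins["baseline_non_acclimatized"].to_numpy(),
        "acclimatized": bins["baseline_acclimatized"].to_numpy(),
    }
    groups = bins["true_group"].to_numpy()
    out = np.empty((len(bins), len(design_table)))
    for j, row in enumerate(design_table.itertuples(index=False)):
        base = base_cols[row.experimental_set]
        factors = np.array([mult[g][row.period] for g in groups])
        out[:, j] = base * factors
    return pd.DataFrame(
        out,
        index=pd.Index(bins["bin_id"], name="bin_id"),
        columns=design_table["sample_id"],
    )


def simulate_coverage(
    true_abundance: pd.DataFrame,
    scaffolds: pd.DataFrame,
    design_table: pd.DataFrame,
    noise_cv: float,
    seed: int,
) -> CoverageMatrix:
    """Scaffold-level coverage from true bin abundances.

    depth(i, s) = A_true(bin(i), s) x lognormal noise (CV = noise_cv)
    x R_s / R_min, so read-count normalization against the lowest-read
    sample inverts the depth factor in expectation (exactly at zero
    noise).
    """
    rng = np.random.default_rng(seed)
    reads = design_table["aligned_reads"].to_numpy(dtype=float)
    depth_factor = reads / reads.min()
    bin_rows = true_abundance.loc[scaffolds["bin_id"]].to_numpy()
    if noise_cv > 0:
        sdlog = np.sqrt(np.log(1.0 + noise_cv**2))
        noise = rng.lognormal(
            -0.5 * sdlog**2, sdlog, size=bin_rows.shape
        )  # mean-1 multiplicative noise
    else:
        noise = 1.0
    depth = bin_rows * noise * depth_factor[None, :]
    depth_df = pd.DataFrame(
        depth,
        index=pd.Index(scaffolds["scaffold_id"], name="scaffold_id"),
        columns=design_table["sample_id"],
    )
    return CoverageMatrix(
        scaffolds=scaffolds[["scaffold_id", "length_bp"]].reset_index(drop=True),
        samples=design_table.reset_index(drop=True),
        depth=depth_df,
    )


def generate_gene_annotations(
    bins: pd.DataFrame, spec: CommunitySpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene -> (bin, category) table with planted enrichments.

    Baseline category membership is multinomial over ``n_categories``
    uniform categories plus the planted ones; in bins whose true group
    is targeted by a planted enrichment, that category's per-gene
    weight is multiplied by the planted fold. A fraction of genes
    carries a second, distinct category to exercise the counting rule.
    Returns the annotation table and the truth table of planted
    (bin, category, fold) rows.
    """
    rng = np.random.default_rng(seed)
    base_cats = [f"cat{str(i + 1).zfill(2)}" for i in range(spec.n_categories)]
    planted_cats = [c for c, _, _ in spec.planted_enrichment]
    categories = base_cats + [c for c in planted_cats if c not in base_cats]
    cat_index = {c: i for i, c in enumerate(categories)}

    rows = []
    truth_rows = []
    gene_counter = 0
    n_cats = len(categories)
    for row in bins.itertuples(index=False):
        # planted categories keep exactly fold x the uniform baseline
        # probability; the others share the remaining mass equally
        probs = np.full(n_cats, 1.0 / n_cats)
        planted_here = []
        for cat, groups, fold in spec.planted_enrichment:
            if row.true_group in groups:
                probs[cat_index[cat]] = fold / n_cats
                planted_here.append(cat_index[cat])
                truth_rows.append(
                    {"bin_id": row.bin_id, "category_id": cat, "fold": fold}
                )
        if planted_here:
            planted_mass = probs[planted_here].sum()
            if planted_mass >= 1.0:
                raise ValueError("planted enrichment folds exceed total probability")
            others = np.setdiff1d(np.arange(n_cats), planted_here)
            probs[others] = (1.0 - planted_mass) / len(others)
        n_genes = int(rng.integers(spec.genes_per_bin[0], spec.genes_per_bin[1] + 1))
        primary = rng.choice(len(categories), size=n_genes, p=probs)
        extra = rng.random(n_genes) < spec.multi_category_rate
        for i in range(n_genes):
            gene_counter += 1
            gene_id = f"gene{gene_counter:06d}"
            rows.append(
                {"gene_id": gene_id, "bin_id": row.bin_id,
                 "category_id": categories[int(primary[i])]}
            )
            if extra[i]:
                second = int(rng.integers(len(categories) - 1))
                if second >= primary[i]:
                    second += 1
                rows.append(
                    {"gene_id": gene_id, "bin_id": row.bin_id,
                     "category_id": categories[second]}
                )
    annotations = pd.DataFrame(rows, columns=["gene_id", "bin_id", "category_id"])
    truth = pd.DataFrame(truth_rows, columns=["bin_id", "category_id", "fold"])
    return annotations, truth


def simulate_process_data(
    design_table: pd.DataFrame,
    design: DesignSpec,
    pspec: ProcessSpec,
    seed: int,
    noise: bool = True,
) -> pd.DataFrame:
    """Daily process records per reactor from deterministic templates.

    Methane yield: flat at ``baseline_yield`` through period I, a
    linear drop to ``baseline x (1 - depth)`` at the (set, dose) nadir
    day, then a damped oscillation toward ``recovered_yield`` (the
    cosine overshoot reproduces the post-dip productivity peak), and an
    exact plateau at ``recovered_yield`` in period III. Total VFA stays
    flat while the acetate/propionate split follows a log-linear
    Ac/Pr trajectory from ``acpr_initial`` (period I) to the
    (set, dose) ``acpr_final`` on the last day. Gaussian noise is
    additive; ``noise=False`` gives the pure templates.
    """
    pspec.validate()
    rng = np.random.default_rng(seed)
    d1_lo, _ = design.period_days["I"]
    dII_lo, dII_hi = design.period_days["II"]
    dIII_lo, dIII_hi = design.period_days["III"]

    reactors = design_table[
        ["reactor_id", "experimental_set", "lcfa_dose"]
    ].drop_duplicates()
    rows = []
    for reac in reactors.itertuples(index=False):
        eset, dose = reac.experimental_set, float(reac.lcfa_dose)
        nadir = pspec.nadir_day[(eset, dose)]
        depth = pspec.inhibition_depth[(eset, dose)]
        y_nadir = pspec.baseline_yield * (1.0 - depth)
        r0 = pspec.acpr_initial[eset]
        r1 = pspec.acpr_final[(eset, dose)]
        for day in range(d1_lo, dIII_hi + 1):
            if day < dII_lo:
                period = "I"
                y = pspec.baseline_yield
            elif day <= dII_hi:
                period = "II"
                if day <= nadir:
                    frac = (day - (dII_lo - 1)) / (nadir - (dII_lo - 1))
                    y = pspec.baseline_yield + frac * (y_nadir - pspec.baseline_yield)
                else:
                    s = day - nadir
                    damp = np.exp(-s / pspec.oscillation_tau_days)
                    y = pspec.recovered_yield - (
                        pspec.recovered_yield - y_nadir
                    ) * damp * np.cos(pspec.oscillation_omega * s)
            else:
                period = "III"
                y = pspec.recovered_yield

            if day < dII_lo:
                ratio = r0
            else:
                frac = (day - (dII_lo - 1)) / (dIII_hi - (dII_lo - 1))
                ratio = float(np.exp(np.log(r0) + frac * (np.log(r1) - np.log(r0))))
            split = pspec.total_vfa - pspec.butyrate
            acetate = split * ratio / (1.0 + ratio)
            propionate = split / (1.0 + ratio)

            if noise:
                y = max(y + rng.normal(0, pspec.noise_sd_yield), 0.0)
                acetate = max(acetate + rng.normal(0, pspec.noise_sd_vfa), 1e-6)
                propionate = max(propionate + rng.normal(0, pspec.noise_sd_vfa), 1e-6)
                ph = float(np.clip(pspec.ph + rng.normal(0, pspec.noise_sd_ph), 0, 14))
                total = acetate + propionate + pspec.butyrate
            else:
                ph = pspec.ph
                total = pspec.total_vfa
            rows.append(
                {
                    "reactor_id": reac.reactor_id,
                    "day": int(day),
                    "methane_yield": float(y),
                    "total_vfa": float(total),
                    "acetate": float(acetate),
                    "propionate": float(propionate),
                    "butyrate": float(pspec.butyrate),
                    "ph": float(ph),
                }
            )
    return pd.DataFrame(rows, columns=PROCESS_COLUMNS)


@dataclass
class SyntheticDataset:
    """In-memory bundle of one generated study."""

    bins: pd.DataFrame
    scaffolds: pd.DataFrame
    bin_map: dict[str, str]
    design: pd.DataFrame
    coverage: CoverageMatrix
    true_abundance: pd.DataFrame
    annotations: pd.DataFrame
    planted_enrichments: pd.DataFrame
    process: pd.DataFrame


def generate_dataset(
    seed: int,
    community: CommunitySpec | None = None,
    design: DesignSpec | None = None,
    process: ProcessSpec | None = None,
    process_noise: bool = True,
) -> SyntheticDataset:
    """Generate a full study under one seed (the module's main entry)."""
    community = community or CommunitySpec()
    design = design or DesignSpec()
    process = process or ProcessSpec()
    root = np.random.SeedSequence(seed)
    s_comm, s_design, s_cov, s_ann, s_proc = [
        int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(5)
    ]
    bins, scaffolds, bin_map = generate_community(community, s_comm)
    design_table = build_design(design, s_design)
    true_abund = simulate_trajectories(bins, design_table, community)
    coverage = simulate_coverage(
        true_abund, scaffolds, design_table, design.noise_cv, s_cov
    )
    annotations, planted = generate_gene_annotations(bins, community, s_ann)
    proc = simulate_process_data(
        design_table, design, process, s_proc, noise=process_noise
    )
    return SyntheticDataset(
        bins=bins,
        scaffolds=scaffolds,
        bin_map=bin_map,
        design=design_table,
        coverage=coverage,
        true_abundance=true_abund,
        annotations=annotations,
        planted_enrichments=planted,
        process=proc,
    )


def write_dataset(dataset: SyntheticDataset, directory: str | Path) -> dict[str, Path]:
    """Write all canonical TSVs plus the truth manifest.

    Files: coverage.tsv, scaffold_bins.tsv, annotations.tsv,
    design.tsv, process.tsv, truth_groups.tsv, truth_enrichment.tsv,
    truth.json. Same seed, same files, byte for byte.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cov = dataset.coverage
    cov_table = pd.concat(
        [
            cov.scaffolds[["scaffold_id", "length_bp"]].reset_index(drop=True),
            cov.depth.reset_index(drop=True),
        ],
        axis=1,
    )
    paths["coverage"] = directory / "coverage.tsv"
    write_report(cov_table, paths["coverage"], sort=True)

    paths["scaffold_bins"] = directory / "scaffold_bins.tsv"
    write_report(
        dataset.scaffolds[["scaffold_id", "bin_id"]], paths["scaffold_bins"], sort=True
    )

    paths["annotations"] = directory / "annotations.tsv"
    write_report(dataset.annotations, paths["annotations"], sort=True)

    paths["design"] = directory / "design.tsv"
    write_report(dataset.design, paths["design"], sort=True)

    paths["process"] = directory / "process.tsv"
    write_report(dataset.process, paths["process"], sort=True)

    paths["truth_groups"] = directory / "truth_groups.tsv"
    write_report(dataset.bins[["bin_id", "true_group"]], paths["truth_groups"], sort=True)

    paths["truth_enrichment"] = directory / "truth_enrichment.tsv"
    write_report(dataset.planted_enrichments, paths["truth_enrichment"], sort=True)

    manifest = {
        "n_bins": int(len(dataset.bins)),
        "n_responsive": int((dataset.bins["true_group"] != "NONE").sum()),
        "n_scaffolds": int(len(dataset.scaffolds)),
        "n_decoys": int(dataset.scaffolds["is_decoy"].sum()),
        "decoy_scaffolds": sorted(
            dataset.scaffolds.loc[dataset.scaffolds["is_decoy"], "scaffold_id"]
        ),
        "n_samples": int(len(dataset.design)),
        "n_planted_enrichments": int(len(dataset.planted_enrichments)),
    }
    paths["truth_manifest"] = directory / "truth.json"
    with open(paths["truth_manifest"], "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
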