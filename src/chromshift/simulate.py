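"""Synthetic annotation, reads, expression and binding data with planted truth.

The generator emulates the statistical structure the analysis assumes, on a
desk-scale genome (default two 10-Mb chromosomes, 2,000 genes), so every
downstream stage is testable without any external download:

* mark reads pile up a few hundred bp downstream of the TSS of
  mark-positive genes over a uniform Poisson background, with the
  repressive-mark distribution wider than the active mark's;
* mark status couples to expression (active-mark-positive genes score high,
  repressive-mark-positive genes low);
* planted between-condition transitions: coordinated switches
  (repressive loss + active gain, and the reverse) carry strong expression
  multipliers, while one-sided switches carry none;
* Smad1 binding clusters sit within 5 kb of target-gene TSSs, plus decoy
  clusters far from all genes;
* a small planted ΔK27 perturbation on some binding targets with coupled
  repression/induction, and three planted promoter-hypermethylation genes
  for the MeDIP screen.

The stored reads emulate a genomic slice of a full sequencing library:
``total_mapped`` (the per-million denominator) is the emulated library size,
not the number of stored reads, which keeps the published RPM thresholds
meaningful at this genome scale.

Reproducibility: every track draws from its own generator seeded from
(master seed, crc32(track label)), so adding a track never perturbs the
others, and regenerating with the same seed is bit-exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneAnnotation, MappedReadSet, READ_COLUMNS

SENESCENCE_SAMPLES = ["MEFp2", "RasV12_d3", "RasV12_d7", "RasV12_d10"]
STIMULATION_SAMPLES = ["BMP_0h", "BMP_3h", "BMP_6h", "BMP_24h"]

TRANSITION_CATEGORIES = {
    # category -> ((k4_A, k27_A), (k4_B, k27_B)) planted mark states
    "K27->K4": ((False, True), (True, False)),
    "Bi->K4": ((True, True), (True, False)),
    "K4->K27": ((True, False), (False, True)),
    "none->K27": ((False, False), (False, True)),
    "k27_loss_other": ((False, True), (False, False)),
    "k27_gain_other": ((True, False), (True, True)),
}

STABLE_CLASSES = {
    # class -> (k4, k27), same in both conditions
    "active": (True, False),
    "silent": (False, False),
    "k27_only": (False, True),
    "bivalent": (True, True),
}


@dataclass(frozen=True)
class SimParams:
    """Generative parameters; the defaults are the study conditions."""

    n_chrom: int = 2
    chrom_length: int = 50_000_000
    n_genes: int = 2000
    gene_length_min: int = 2000
    gene_length_max: int = 50000
    min_gap: int = 6000  # keeps each TSS flank attributable to its own gene
    read_length: int = 36
    total_mapped: int = 10_000_000  # emulated library size (RPM denominator)
    background_per_bp: float = 0.0015  # stored background reads per track

    # mark read placement: 5' offsets ~ Normal(mean, sd) downstream of TSS
    k4_budget: float = 350.0
    k4_offset_mean: float = 250.0
    k4_offset_sd: float = 300.0
    k27_budget: float = 180.0
    k27_offset_mean: float = 500.0
    k27_offset_sd: float = 700.0
    medip_budget: float = 150.0
    medip_offset_sd: float = 400.0

    # planted transition fractions (of all genes)
    frac_k27_to_k4: float = 0.02
    frac_k4_to_k27: float = 0.005
    frac_bi_to_k4: float = 0.05
    frac_none_to_k27: float = 0.09
    frac_k27_loss_other: float = 0.03
    frac_k27_gain_other: float = 0.01

    # stable genes split across baseline mark classes (weights, normalized)
    stable_weights: tuple = (("active", 0.50), ("silent", 0.37),
                             ("k27_only", 0.07), ("bivalent", 0.06))

    # expression model
    expr_class_means: tuple = (("active", 300.0), ("silent", 25.0),
                               ("k27_only", 8.0), ("bivalent", 12.0))
    expr_log_sd: float = 0.8
    noise_log_sd: float = 0.2
    up_mult_range: tuple = (5.0, 100.0)
    down_mult_range: tuple = (0.01, 0.2)

    # Smad1 binding
    target_fraction: float = 0.05
    smad1_cluster_budget: float = 30.0
    smad1_cluster_sd: float = 60.0
    smad1_offset_range: int = 5000
    decoy_fraction: float = 0.2
    induction_range: tuple = (3.0, 10.0)

    # planted ΔK27 strata on targets, with coupled senescence expression
    target_delta_up_frac: float = 0.10
    target_delta_down_frac: float = 0.15
    delta_k27_extra_reads: float = 40.0
    delta_up_expr_range: tuple = (0.05, 0.3)
    delta_down_expr_range: tuple = (3.0, 15.0)

    # MeDIP planting
    n_medip_methylated: int = 100  # methylated in both conditions
    n_medip_hyper: int = 3  # gain methylation in the second condition

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    def genome(self) -> dict[str, int]:
        return {c: self.chrom_length for c in self.chrom_names()}


def track_rng(seed: int, label: str) -> np.random.Generator:
    """One independent stream per track, keyed by (master seed, label)."""
    return np.random.default_rng([int(seed) % (2**31),
                                  zlib.crc32(label.encode()) & 0x7FFFFFFF])


def simulate_annotation(params: SimParams, seed: int) -> GeneAnnotation:
    """Non-overlapping genes of length 2-50 kb placed uniformly.

    Placement draws the gene lengths, then distributes the leftover sequence
    as uniform random gaps (order statistics of uniforms), which samples
    non-overlapping uniform placements directly instead of rejection; every
    intergenic gap is at least ``min_gap`` so a gene's TSS flank cannot sit
    on a neighbour's promoter signal.  Raises when the requested genes
    cannot fit on the chromosome.
    """
    rng = track_rng(seed, "annotation")
    per_chrom = np.full(params.n_chrom, params.n_genes // params.n_chrom)
    per_chrom[: params.n_genes % params.n_chrom] += 1
    rows = []
    for chrom, n in zip(params.chrom_names(), per_chrom):
        lengths = rng.integers(params.gene_length_min,
                               params.gene_length_max + 1, size=n)
        free = (params.chrom_length - int(lengths.sum())
                - (n + 1) * params.min_gap)
        if free < 0:
            raise RuntimeError("gene density infeasible: genes cannot fit")
        cuts = np.sort(rng.integers(0, free + 1, size=n))
        starts = (cuts + np.concatenate(([0], np.cumsum(lengths[:-1])))
                  + params.min_gap * np.arange(1, n + 1))
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        for s, ln, strand in zip(starts, lengths, strands):
            rows.append((chrom, int(s), int(s + ln), strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df.insert(0, "gene_id", [f"g{i:05d}" for i in range(len(df))])
    return GeneAnnotation(genes=df)


def plant_transitions(annotation: GeneAnnotation, params: SimParams,
                      seed: int) -> pd.DataFrame:
    """Per-gene planted truth: mark states, category, expression multiplier,
    binding-target flag, ΔK27 class, MeDIP class."""
    rng = track_rng(seed, "truth")
    gene_ids = list(annotation.genes["gene_id"])
    n = len(gene_ids)
    fracs = [("K27->K4", params.frac_k27_to_k4),
             ("K4->K27", params.frac_k4_to_k27),
             ("Bi->K4", params.frac_bi_to_k4),
             ("none->K27", params.frac_none_to_k27),
             ("k27_loss_other", params.frac_k27_loss_other),
             ("k27_gain_other", params.frac_k27_gain_other)]
    if sum(f for _, f in fracs) > 1:
        raise ValueError("transition fractions sum above 1")

    category = np.array(["stable"] * n, dtype=object)
    perm = rng.permutation(n)
    pos = 0
    for cat, frac in fracs:
        k = int(round(frac * n))
        category[perm[pos:pos + k]] = cat
        pos += k

    names, weights = zip(*params.stable_weights)
    w = np.asarray(weights, dtype=float)
    w /= w.sum()
    stable_class = rng.choice(names, size=n, p=w)

    k4_a = np.empty(n, bool)
    k27_a = np.empty(n, bool)
    k4_b = np.empty(n, bool)
    k27_b = np.empty(n, bool)
    for i in range(n):
        if category[i] == "stable":
            k4, k27 = STABLE_CLASSES[stable_class[i]]
            k4_a[i] = k4_b[i] = k4
            k27_a[i] = k27_b[i] = k27
        else:
            (a4, a27), (b4, b27) = TRANSITION_CATEGORIES[category[i]]
            k4_a[i], k27_a[i], k4_b[i], k27_b[i] = a4, a27, b4, b27

    # expression class from the baseline mark state
    expr_class = np.where(k27_a, np.where(k4_a, "bivalent", "k27_only"),
                          np.where(k4_a, "active", "silent"))

    multiplier = np.ones(n)
    up = category == "K27->K4"
    multiplier[up] = rng.uniform(*params.up_mult_range, size=up.sum())
    down = category == "K4->K27"
    multiplier[down] = rng.uniform(*params.down_mult_range, size=down.sum())

    # Smad1 targets from stable genes only, so binding truth never collides
    # with planted transitions
    stable_idx = np.flatnonzero(category == "stable")
    n_targets = int(round(params.target_fraction * n))
    target_idx = rng.choice(stable_idx, size=n_targets, replace=False)
    is_target = np.zeros(n, bool)
    is_target[target_idx] = True
    induction = np.ones(n)
    induction[target_idx] = rng.uniform(*params.induction_range,
                                        size=n_targets)

    # ΔK27 strata on targets: extra repressive-mark reads in one condition,
    # with coupled senescence expression change
    delta_class = np.array(["none"] * n, dtype=object)
    tperm = rng.permutation(target_idx)
    n_up = int(round(params.target_delta_up_frac * n_targets))
    n_down = int(round(params.target_delta_down_frac * n_targets))
    up_idx, down_idx = tperm[:n_up], tperm[n_up:n_up + n_down]
    delta_class[up_idx] = "increase"
    delta_class[down_idx] = "decrease"
    extra_k27_a = np.zeros(n)
    extra_k27_b = np.zeros(n)
    extra_k27_b[up_idx] = params.delta_k27_extra_reads
    extra_k27_a[down_idx] = params.delta_k27_extra_reads
    multiplier[up_idx] = rng.uniform(*params.delta_up_expr_range, size=n_up)
    multiplier[down_idx] = rng.uniform(*params.delta_down_expr_range,
                                       size=n_down)

    # MeDIP: constitutively methylated promoters plus a few hypermethylated
    medip = np.array(["none"] * n, dtype=object)
    mperm = rng.permutation(n)
    medip[mperm[:params.n_medip_methylated]] = "methylated"
    medip[mperm[params.n_medip_methylated:
                params.n_medip_methylated + params.n_medip_hyper]] = "hyper"

    return pd.DataFrame({
        "gene_id": gene_ids, "category": category,
        "stable_class": stable_class, "expr_class": expr_class,
        "k4_A": k4_a, "k4_B": k4_b, "k27_A": k27_a, "k27_B": k27_b,
        "multiplier": multiplier, "is_target": is_target,
        "induction": induction, "delta_k27_class": delta_class,
        "extra_k27_A": extra_k27_a, "extra_k27_B": extra_k27_b,
        "medip_class": medip,
    }).set_index("gene_id")


def _reads_frame(chroms: list[str], positions: list[np.ndarray],
                 strands: list[np.ndarray], params: SimParams) -> pd.DataFrame:
    """Assemble BED-like reads whose 5' anchor equals the given positions."""
    rl = params.read_length
    frames = []
    for chrom, pos, strand in zip(chroms, positions, strands):
        pos = np.clip(pos, rl - 1, params.chrom_length - rl)
        start = np.where(strand, pos - (rl - 1), pos)
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "start": start.astype(np.int64),
            "end": (start + rl).astype(np.int64),
            "strand": np.where(strand, "-", "+"),
        }))
    if not frames:
        return pd.DataFrame({c: pd.Series(dtype=t) for c, t in
                             zip(READ_COLUMNS, [str, np.int64, np.int64, str])})
    return pd.concat(frames, ignore_index=True)


def _background_positions(params: SimParams, rng: np.random.Generator,
                          rate_per_bp: float) -> tuple[list, list, list]:
    chroms, positions, strands = [], [], []
    for chrom in params.chrom_names():
        k = rng.poisson(rate_per_bp * params.chrom_length)
        chroms.append(chrom)
        positions.append(rng.integers(0, params.chrom_length, size=k))
        strands.append(rng.random(k) < 0.5)
    return chroms, positions, strands


def simulate_mark_reads(annotation: GeneAnnotation, positive: np.ndarray,
                        params: SimParams, seed: int, *, label: str,
                        budget: float, offset_mean: float, offset_sd: float,
                        extra: np.ndarray | None = None) -> MappedReadSet:
    """Reads for one (mark, condition) track.

    ``positive`` is a boolean vector in annotation order; positive genes
    receive Poisson(budget) reads with 5' offsets Normal(offset_mean,
    offset_sd) downstream of the TSS in transcription direction, over a
    uniform Poisson background.  ``extra`` adds per-gene extra read budget
    (for planted ΔK27 strata) independent of status.
    """
    rng = track_rng(seed, label)
    chroms, positions, strands = _background_positions(
        params, rng, params.background_per_bp)
    genes = annotation.genes
    tss = genes["tss"].to_numpy(np.int64)
    sign = np.where(genes["strand"].to_numpy() == "-", -1, 1)
    budgets = np.where(positive, budget, 0.0)
    if extra is not None:
        budgets = budgets + extra
    counts = rng.poisson(budgets)
    for i in np.flatnonzero(counts):
        k = int(counts[i])
        offs = np.rint(rng.normal(offset_mean, offset_sd, size=k)).astype(np.int64)
        chroms.append(genes["chrom"].iloc[i])
        positions.append(tss[i] + sign[i] * offs)
        strands.append(rng.random(k) < 0.5)
    reads = _reads_frame(chroms, positions, strands, params)
    return MappedReadSet(sample_id=label, reads=reads,
                         total_mapped=params.total_mapped)


def simulate_smad1_reads(annotation: GeneAnnotation, target: np.ndarray,
                         params: SimParams, seed: int,
                         label: str = "smad1") -> MappedReadSet:
    """Binding-factor reads: one tight cluster near each target TSS, decoy
    clusters far from all genes, uniform background."""
    rng = track_rng(seed, label)
    chroms, positions, strands = _background_positions(
        params, rng, params.background_per_bp)
    genes = annotation.genes
    tss = genes["tss"].to_numpy(np.int64)
    cluster_centers = []
    for i in np.flatnonzero(target):
        center = int(tss[i] + rng.integers(-params.smad1_offset_range,
                                           params.smad1_offset_range + 1))
        cluster_centers.append((genes["chrom"].iloc[i], center))
    # decoys: clusters placed > 10 kb away from every gene span
    n_decoys = int(round(params.decoy_fraction * int(target.sum())))
    spans = {c: g[["start", "end"]].to_numpy(np.int64)
             for c, g in genes.groupby("chrom", sort=False)}
    names = params.chrom_names()
    placed = 0
    attempts = 0
    while placed < n_decoys and attempts < 1000 * max(n_decoys, 1):
        attempts += 1
        chrom = names[int(rng.integers(len(names)))]
        center = int(rng.integers(20000, params.chrom_length - 20000))
        sp = spans.get(chrom)
        if sp is not None and ((center >= sp[:, 0] - 10000)
                               & (center < sp[:, 1] + 10000)).any():
            continue
        cluster_centers.append((chrom, center))
        placed += 1
    for chrom, center in cluster_centers:
        k = int(rng.poisson(params.smad1_cluster_budget))
        chroms.append(chrom)
        positions.append(np.rint(rng.normal(
            center, params.smad1_cluster_sd, size=k)).astype(np.int64))
        strands.append(rng.random(k) < 0.5)
    reads = _reads_frame(chroms, positions, strands, params)
    return MappedReadSet(sample_id=label, reads=reads,
                         total_mapped=params.total_mapped)


def simulate_expression(truth: pd.DataFrame, params: SimParams,
                        seed: int) -> ExpressionMatrix:
    """Baseline + three senescence time points + a stimulation time course.

    Baseline scores are lognormal with a class mean set by the baseline mark
    state; senescence-day scores multiply in the planted fold multiplier and
    per-day lognormal noise; in the stimulation course, binding targets are
    induced from the first post-stimulation time point on.
    """
    rng = track_rng(seed, "expression")
    n = len(truth)
    means = dict(params.expr_class_means)
    class_mean = truth["expr_class"].map(means).to_numpy(float)
    # lognormal with the requested arithmetic mean
    mu = np.log(class_mean) - params.expr_log_sd**2 / 2
    baseline = np.exp(rng.normal(mu, params.expr_log_sd))
    mult = truth["multiplier"].to_numpy(float)
    induction = truth["induction"].to_numpy(float)

    def noisy(values: np.ndarray) -> np.ndarray:
        if params.noise_log_sd == 0:
            return values.copy()
        return values * np.exp(rng.normal(-params.noise_log_sd**2 / 2,
                                          params.noise_log_sd, size=n))

    data = {"MEFp2": noisy(baseline)}
    for day in SENESCENCE_SAMPLES[1:]:
        data[day] = noisy(baseline * mult)
    data["BMP_0h"] = noisy(baseline)
    for t in STIMULATION_SAMPLES[1:]:
        data[t] = noisy(baseline * induction)
    scores = pd.DataFrame(data, index=truth.index).T
    scores.columns.name = "gene_id"
    return ExpressionMatrix(scores=scores)


@dataclass
class SimBundle:
    params: SimParams
    seed: int
    annotation: GeneAnnotation
    truth: pd.DataFrame
    readsets: dict[str, MappedReadSet]
    expression: ExpressionMatrix
    genome: dict[str, int] = field(default_factory=dict)


def simulate_bundle(params: SimParams = SimParams(), seed: int = 0) -> SimBundle:
    """Generate the full input bundle with planted ground truth."""
    annotation = simulate_annotation(params, seed)
    truth = plant_transitions(annotation, params, seed)
    readsets = {}
    for cond in ("A", "B"):
        readsets[f"k4_{cond}"] = simulate_mark_reads(
            annotation, truth[f"k4_{cond}"].to_numpy(), params, seed,
            label=f"k4_{cond}", budget=params.k4_budget,
            offset_mean=params.k4_offset_mean, offset_sd=params.k4_offset_sd)
        readsets[f"k27_{cond}"] = simulate_mark_reads(
            annotation, truth[f"k27_{cond}"].to_numpy(), params, seed,
            label=f"k27_{cond}", budget=params.k27_budget,
            offset_mean=params.k27_offset_mean, offset_sd=params.k27_offset_sd,
            extra=truth[f"extra_k27_{cond}"].to_numpy())
        medip_pos = ((truth["medip_class"] == "methylated")
                     | ((truth["medip_class"] == "hyper") & (cond == "B")))
        readsets[f"medip_{cond}"] = simulate_mark_reads(
            annotation, medip_pos.to_numpy(), params, seed,
            label=f"medip_{cond}", budget=params.medip_budget,
            offset_mean=0.0, offset_sd=params.medip_offset_sd)
    readsets["smad1"] = simulate_smad1_reads(
        annotation, truth["is_target"].to_numpy(), params, seed)
    expression = simulate_expression(truth, params, seed)
    return SimBundle(params=params, seed=seed, annotation=annotation,
                     truth=truth, readsets=readsets, expression=expression,
                     genome=params.genome())


def truth_transition_frame(truth: pd.DataFrame) -> pd.DataFrame:
    """Pseudo transition table from planted truth (category + repressive-mark
    panel membership), for testing enrichment against known categories."""
    loss = {"K27->K4", "Bi->K4", "k27_loss_other"}
    gain = {"K4->K27", "none->K27", "k27_gain_other"}
    k27_tr = np.where(truth["category"].isin(loss), "loss",
                      np.where(truth["category"].isin(gain), "gain", "stable"))
    return pd.DataFrame({"category": truth["category"],
                         "k27_transition": k27_tr}, index=truth.index)


def params_manifest(params: SimParams, seed: int) -> dict:
    d = asdict(params)
    d["seed"] = seed
    return d
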