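"""Synthetic data with known ground truth for every pipeline stage.

Emulates the statistical structure of a developmental cone
photoreceptor time course: 13 postnatal days x 3 replicates of
negative-binomial RNA-seq counts in which ~14% of expressed genes
switch abruptly at day 6 (logistic in time, scale 0.25 days, so the
transition runs from day 5 to day 7); transcription-factor labels at a
6% background rate but enriched in the strongest switch-off tail;
coupled exonic/intronic dynamics with a tunable transcriptional
fraction; and ATAC peaks whose probability of losing accessibility
between day 3 and day 6 falls with planted CTCF-motif content and
rises with distance from the nearest TSS.

All randomness derives from ``SimulationConfig.seed`` through spawned
``numpy.random.SeedSequence`` streams (one child per stage), so outputs
are byte-identical across runs and platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CountMatrix, GeneAnnotation, GenomicInterval
from .pwm import PWMModel, count_hits, reverse_complement


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Ground-truth parameters of the synthetic study.

    Class fractions apply to the expressed-gene universe; an extra
    ``low_expression_rate`` of genes sits below the detection threshold
    to create the bimodal abundance structure the threshold-selection
    step assumes.
    """

    # expression time course
    n_genes: int = 2000                 # expressed genes
    days: tuple = tuple(range(13))
    n_replicates: int = 3
    switch_day: int = 6
    switch_scale_days: float = 0.25     # logistic time scale
    frac_switch_on: float = 0.045
    frac_switch_off: float = 0.095      # on + off = 0.14
    frac_constant: float = 0.15
    effect_log2_min: float = 1.0        # switch magnitude = min + Exp(scale)
    effect_log2_scale: float = 1.5      # 2- to ~1000-fold changes
    effect_log2_max: float = 10.0
    other_delta_sd: float = 0.3         # mild drift of unclassified genes
    low_expression_rate: float = 0.3    # sub-threshold genes, per expressed
    expressed_log2_rpkm_mean: float = 4.0
    expressed_log2_rpkm_sd: float = 1.5
    low_log2_rpkm_mean: float = -4.0
    low_log2_rpkm_sd: float = 1.0
    nb_dispersion: float = 0.05
    library_size_mean: float = 2e6
    library_size_sigma: float = 0.25    # lognormal depth variation
    # gene labels
    tf_background_frac: float = 0.06
    tf_enrichment_in_off: float = 0.23  # TF fraction in the top-100 off tail
    n_cone_specific: int = 41
    # exon/intron coupling
    transcriptional_fraction: float = 0.72   # calibrated: recovered r ~ 0.84
    intron_depth_ratio: float = 0.6
    intron_dispersion: float = 0.01     # conditional on realized pre-mRNA
    #                                     the intron count noise is mostly
    #                                     technical, tighter than biological
    # ATAC peaks
    n_peaks: int = 5000
    peak_cell_bp: int = 5000            # one peak per genomic cell
    frac_proximal: float = 0.2          # promoter-like peaks with a TSS
    promoter_width_log_mean: float = 6.8   # ln bp ~ 900
    enhancer_width_log_mean: float = 5.86  # ln bp ~ 350
    peak_width_log_sd: float = 0.25
    peak_min_width: int = 150
    peak_max_width: int = 2400
    ctcf_lambda: float = 1.0            # planted CTCF sites per peak
    decoy_lambda: float = 0.4
    loss_logit_coefs: tuple = (-4.825, -1.4, 1.1, -0.9)
    #                          b0, per CTCF site, per log10 bp, per kb width
    gain_prob: float = 0.025            # day3->6 gains, independent of CTCF
    late_change_prob: float = 0.0005    # day6->10 changes, rare
    accessibility_effect_log2: tuple = (1.5, 3.5)  # |log2 FC| range of changes
    peak_mean_log: float = 4.1          # ln baseline counts ~ 60
    peak_mean_log_sd: float = 0.5
    atac_days: tuple = (3, 6, 10)
    atac_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (self.frac_switch_on, self.frac_switch_off, self.frac_constant)
        if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1:
            raise ValueError("class fractions must lie in [0,1] and sum <= 1")
        if not 0 <= self.transcriptional_fraction <= 1:
            raise ValueError("transcriptional_fraction must lie in [0,1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class TruthTable:
    """Ground truth: per-gene class/effect and per-peak change labels."""

    genes: pd.DataFrame = None   # class, delta_log2, base_log2_rpkm, ...
    peaks: pd.DataFrame = None   # true_class_3_6, ctcf_sites, ...


def _child_rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, stage]))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: NB(mean, var = mean + dispersion * mean^2)."""
    mean = np.maximum(mean, 1e-12)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


# ------------------------------------------------------------- expression

def _assign_classes(cfg: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    n_on = round(cfg.frac_switch_on * n)
    n_off = round(cfg.frac_switch_off * n)
    n_const = round(cfg.frac_constant * n)
    n_low = round(cfg.low_expression_rate * n)
    classes = np.array(
        ["switch_on"] * n_on + ["switch_off"] * n_off
        + ["constant"] * n_const + ["other"] * (n - n_on - n_off - n_const),
        dtype=object)
    rng.shuffle(classes)
    classes = np.concatenate([classes, np.array(["low"] * n_low, dtype=object)])

    n_total = n + n_low
    gene_ids = np.array([f"gene{i:05d}" for i in range(n_total)], dtype=object)
    base = np.where(
        classes == "low",
        rng.normal(cfg.low_log2_rpkm_mean, cfg.low_log2_rpkm_sd, n_total),
        rng.normal(cfg.expressed_log2_rpkm_mean, cfg.expressed_log2_rpkm_sd,
                   n_total))
    magnitude = np.minimum(
        cfg.effect_log2_min + rng.exponential(cfg.effect_log2_scale, n_total),
        cfg.effect_log2_max)
    delta = np.zeros(n_total)
    delta[classes == "switch_on"] = magnitude[classes == "switch_on"]
    delta[classes == "switch_off"] = -magnitude[classes == "switch_off"]
    other = classes == "other"
    delta[other] = np.clip(rng.normal(0.0, cfg.other_delta_sd, other.sum()),
                           -0.8, 0.8)
    # switch genes peak at their drawn base level: on genes start low and
    # rise to it, off genes start there and fall, mirroring real switch
    # genes that are expressed on only one side of the transition
    pre = base - np.clip(delta, 0.0, None)
    # transcriptional flags: exact count among expressed genes
    expressed = classes != "low"
    n_trans = round(cfg.transcriptional_fraction * expressed.sum())
    trans = np.zeros(n_total, dtype=bool)
    idx = np.flatnonzero(expressed)
    trans[rng.permutation(idx)[:n_trans]] = True

    length = np.clip(np.exp(rng.normal(np.log(1500), 0.5, n_total)),
                     200, 20000).astype(int)
    # normalize so the pre-switch state's total intensity matches the
    # RPKM identity (sum of rpkm * length = 1e9): measured RPKM then
    # tracks the intended scale and the abundance modes sit where the
    # config puts them
    shift = np.log2(np.sum(2.0 ** pre * length) / 1e9)
    pre = pre - shift
    return pd.DataFrame({
        "class": classes, "pre_log2_rpkm": pre, "delta_log2": delta,
        "transcriptional": trans, "length_bp": length,
    }, index=gene_ids)


def _assign_tf_labels(cfg: SimulationConfig, genes: pd.DataFrame,
                      rng: np.random.Generator) -> np.ndarray:
    """TF labels hitting the background fraction globally and the target
    fraction in the strongest switch-off tail (top 100 by true effect)."""
    expressed = genes["class"] != "low"
    n_exp = int(expressed.sum())
    n_tf = round(cfg.tf_background_frac * n_exp)
    tail_size = min(100, n_exp)
    n_tail_tf = round(cfg.tf_enrichment_in_off * tail_size)
    if n_tail_tf > n_tf:
        raise ValueError(
            f"infeasible enrichment: {n_tail_tf} TFs demanded in the off "
            f"tail but only {n_tf} TFs exist")
    order = genes.loc[expressed, "delta_log2"].sort_values().index
    tail = order[:tail_size]
    rest = order[tail_size:]
    is_tf = pd.Series(False, index=genes.index)
    is_tf[rng.permutation(np.asarray(tail, dtype=object))[:n_tail_tf]] = True
    n_rest = n_tf - n_tail_tf
    if n_rest > len(rest):
        raise ValueError("infeasible enrichment: too few genes outside tail")
    is_tf[rng.permutation(np.asarray(rest, dtype=object))[:n_rest]] = True
    return is_tf.to_numpy()


def _build_pathways(cfg: SimulationConfig, genes: pd.DataFrame,
                    rng: np.random.Generator) -> tuple[pd.Series, np.ndarray]:
    """Biased (on/off) and null pathway memberships + cone-specific set."""
    on_pool = np.asarray(genes.index[genes["class"] == "switch_on"],
                         dtype=object)
    off_pool = np.asarray(genes.index[genes["class"] == "switch_off"],
                          dtype=object)
    expressed = np.asarray(genes.index[genes["class"] != "low"], dtype=object)
    sets = {
        "phototransduction_like": rng.choice(
            on_pool, size=min(30, len(on_pool)), replace=False),
        "axon_guidance_like": rng.choice(
            off_pool, size=min(35, len(off_pool)), replace=False),
    }
    for i in range(3):
        sets[f"null_pathway_{i + 1}"] = rng.choice(
            expressed, size=30, replace=False)
    pathways = pd.Series([set() for _ in range(len(genes))],
                         index=genes.index)
    for name, members in sets.items():
        for g in members:
            pathways[g].add(name)
    n_from_on = min(cfg.n_cone_specific - 6, len(on_pool))
    cone = np.concatenate([
        rng.choice(on_pool, size=n_from_on, replace=False),
        rng.choice(expressed, size=cfg.n_cone_specific - n_from_on,
                   replace=False)])
    is_cone = np.isin(np.asarray(genes.index, dtype=object), cone)
    return pathways, is_cone


def _expression_count_means(cfg: SimulationConfig, genes: pd.DataFrame,
                            lib: np.ndarray, day: np.ndarray) -> np.ndarray:
    """Expected counts per gene per sample from the logistic time course."""
    t = _sigmoid((day[None, :] - cfg.switch_day) / cfg.switch_scale_days)
    log2_rpkm = (genes["pre_log2_rpkm"].to_numpy()[:, None]
                 + genes["delta_log2"].to_numpy()[:, None] * t)
    rpkm_true = 2.0 ** log2_rpkm
    length = genes["length_bp"].to_numpy()[:, None]
    return rpkm_true * length * lib[None, :] / 1e9


def simulate_expression(cfg: SimulationConfig,
                        ) -> tuple[CountMatrix, GeneAnnotation, TruthTable]:
    """Gene-level NB counts, annotation, and the gene truth table."""
    rng = _child_rng(cfg.seed, 1)
    genes = _assign_classes(cfg, rng)
    is_tf = _assign_tf_labels(cfg, genes, rng)
    pathways, is_cone = _build_pathways(cfg, genes, rng)
    genes["is_tf"] = is_tf
    genes["is_cone_specific"] = is_cone

    n_samples = len(cfg.days) * cfg.n_replicates
    day = np.repeat(np.asarray(cfg.days), cfg.n_replicates)
    replicate = np.tile(np.arange(cfg.n_replicates), len(cfg.days))
    lib = np.exp(rng.normal(np.log(cfg.library_size_mean),
                            cfg.library_size_sigma, n_samples))
    mean = _expression_count_means(cfg, genes, lib, day)
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)

    sample_ids = np.array([f"P{d}_r{r + 1}" for d, r in zip(day, replicate)],
                          dtype=object)
    cm = CountMatrix(np.asarray(genes.index, dtype=object), sample_ids, day,
                     replicate, counts, genes["length_bp"].to_numpy())

    chroms = np.array([f"chr{c}" for c in
                       rng.integers(1, 20, size=len(genes))], dtype=object)
    ann = GeneAnnotation(pd.DataFrame({
        "chromosome": chroms,
        "tss_bp": rng.integers(0, 100_000_000, size=len(genes)),
        "strand": rng.choice(["+", "-"], size=len(genes)),
        "is_tf": is_tf,
        "is_cone_specific": is_cone,
        "pathways": pathways,
    }, index=genes.index))
    return cm, ann, TruthTable(genes=genes)


# ------------------------------------------------------------ exon / intron

def simulate_exon_intron(cfg: SimulationConfig, truth: TruthTable,
                         ) -> tuple[CountMatrix, CountMatrix]:
    """Coupled exonic and intronic count matrices.

    Exonic counts follow the gene truth time course.  For genes flagged
    transcriptional the intronic expected count tracks the *realized*
    exonic count (pre-mRNA moves with transcription, so the intron
    change equals the exon change up to counting noise); for the
    remainder the intronic level stays flat at the pre-switch baseline
    (post-transcriptional regulation leaves pre-mRNA unchanged).
    """
    rng = _child_rng(cfg.seed, 2)
    genes = truth.genes
    n_samples = len(cfg.days) * cfg.n_replicates
    day = np.repeat(np.asarray(cfg.days), cfg.n_replicates)
    replicate = np.tile(np.arange(cfg.n_replicates), len(cfg.days))
    lib = np.exp(rng.normal(np.log(cfg.library_size_mean),
                            cfg.library_size_sigma, n_samples))
    exon_mean = _expression_count_means(cfg, genes, lib, day)
    exon_counts = _nb_draw(rng, exon_mean, cfg.nb_dispersion)

    trans = genes["transcriptional"].to_numpy()
    baseline_mean = (2.0 ** genes["pre_log2_rpkm"].to_numpy()[:, None]
                     * genes["length_bp"].to_numpy()[:, None]
                     * lib[None, :] / 1e9)
    intron_mean = np.where(trans[:, None],
                           cfg.intron_depth_ratio * exon_counts,
                           cfg.intron_depth_ratio * baseline_mean)
    intron_counts = _nb_draw(rng, intron_mean, cfg.intron_dispersion)

    sample_ids = np.array([f"P{d}_r{r + 1}" for d, r in zip(day, replicate)],
                          dtype=object)
    lengths = genes["length_bp"].to_numpy()
    make = lambda c: CountMatrix(np.asarray(genes.index, dtype=object),
                                 sample_ids.copy(), day.copy(),
                                 replicate.copy(), c, lengths)
    return make(exon_counts), make(intron_counts)


# ------------------------------------------------------------------- motifs

_CTCF_LIKE_DOMINANT = "CCGCGAGGTGGCAGTGCCC"  # synthetic CTCF-like consensus


def _pwm_from_dominant(motif_id: str, dominant: str,
                       strong: float = 85.0, weak: float = 5.0) -> PWMModel:
    counts = np.full((4, len(dominant)), weak)
    for j, base in enumerate(dominant):
        counts["ACGT".index(base), j] = strong
    return PWMModel(motif_id, counts)


def default_motif_library(n_decoys: int = 8,
                          decoy_length: int = 12) -> list[PWMModel]:
    """Packaged synthetic motif library: a CTCF-like PWM first, then
    seeded decoy PWMs.  Fixed internally so the generator and any
    downstream scan agree on the same library regardless of the
    simulation seed."""
    rng = np.random.default_rng(20160101)
    models = [_pwm_from_dominant("CTCF_like", _CTCF_LIKE_DOMINANT)]
    for i in range(n_decoys):
        dom = "".join(rng.choice(list("ACGT"), size=decoy_length))
        models.append(_pwm_from_dominant(f"decoy_{i + 1:02d}", dom))
    return models


@dataclass
class PeakSimulation:
    """Bundle of every ATAC-stage input plus ground truth."""

    genome: dict[str, str]
    intervals: list[GenomicInterval]
    counts: np.ndarray        # peaks x samples
    day: np.ndarray
    replicate: np.ndarray
    sample_ids: np.ndarray
    tss_annotation: GeneAnnotation
    truth: TruthTable
    motif_library: list[PWMModel] = field(default_factory=list)


def _plant(seq: bytearray, motif: str, offsets_taken: list,
           rng: np.random.Generator, n: int) -> int:
    """Plant up to n non-overlapping copies (random strand); returns the
    number actually placed."""
    L = len(motif)
    if L > len(seq):
        raise ValueError("planted motif longer than peak")
    placed = 0
    for _ in range(n):
        for _attempt in range(100):
            off = int(rng.integers(0, len(seq) - L + 1))
            if all(off + L <= a or off >= b for a, b in offsets_taken):
                instance = motif if rng.random() < 0.5 \
                    else reverse_complement(motif)
                seq[off:off + L] = instance.encode()
                offsets_taken.append((off, off + L))
                placed += 1
                break
    return placed


def simulate_peaks(cfg: SimulationConfig,
                   motif_library: list[PWMModel] | None = None,
                   ) -> PeakSimulation:
    """ATAC peaks on a synthetic chromosome with planted motifs.

    One peak per ``peak_cell_bp`` genomic cell (so peaks never overlap);
    a ``frac_proximal`` subset carries a TSS near its midpoint
    (promoter-like, wider), the rest are enhancer-like (shorter,
    distal).  CTCF-like sites are planted at Poisson(ctcf_lambda) per
    peak; the probability of accessibility loss between the first two
    timepoints follows a logistic model in scanned CTCF count,
    log10 TSS distance and width.  The truth table's CTCF counts are
    the scanner's own counts on the emitted sequence, so planting and
    scanning agree exactly by construction.
    """
    if motif_library is None:
        motif_library = default_motif_library()
    ctcf = motif_library[0]
    decoys = motif_library[1:]
    rng = _child_rng(cfg.seed, 3)

    n = cfg.n_peaks
    cell = cfg.peak_cell_bp
    genome_len = n * cell
    codes = rng.integers(0, 4, size=genome_len, dtype=np.int8)
    genome_arr = bytearray(np.frombuffer(b"ACGT", dtype=np.uint8)[codes]
                           .tobytes())

    cell_start = np.arange(n) * cell
    mid = cell_start + cell // 2 + rng.integers(-400, 401, size=n)
    proximal = rng.random(n) < cfg.frac_proximal
    log_mean = np.where(proximal, cfg.promoter_width_log_mean,
                        cfg.enhancer_width_log_mean)
    width = np.clip(np.exp(rng.normal(log_mean, cfg.peak_width_log_sd)),
                    cfg.peak_min_width, cfg.peak_max_width).astype(int)
    start = mid - width // 2
    end = start + width

    tss = np.sort(mid[proximal] + rng.integers(-250, 251,
                                               size=int(proximal.sum())))
    if tss.size == 0:
        raise ValueError("no proximal peaks: cannot place any TSS")
    j = np.searchsorted(tss, mid)
    left = tss[np.clip(j - 1, 0, tss.size - 1)]
    right = tss[np.clip(j, 0, tss.size - 1)]
    distance = np.minimum(np.abs(mid - left), np.abs(mid - right))

    n_ctcf_planted = rng.poisson(cfg.ctcf_lambda, size=n)
    n_decoy_planted = rng.poisson(cfg.decoy_lambda, size=(n, len(decoys)))
    for i in range(n):
        seq = bytearray(genome_arr[start[i]:end[i]])
        taken: list = []
        _plant(seq, ctcf.consensus, taken, rng, int(n_ctcf_planted[i]))
        for d, pwm in enumerate(decoys):
            _plant(seq, pwm.consensus, taken, rng, int(n_decoy_planted[i, d]))
        genome_arr[start[i]:end[i]] = seq

    genome = {"chrSim": genome_arr.decode()}
    intervals = [GenomicInterval("chrSim", int(s), int(e), f"peak{i:05d}")
                 for i, (s, e) in enumerate(zip(start, end))]
    peak_seqs = [genome["chrSim"][s:e] for s, e in zip(start, end)]
    ctcf_scanned = np.array([count_hits(s, ctcf) for s in peak_seqs])

    b0, b_ctcf, b_dist, b_width = cfg.loss_logit_coefs
    loss_p = _sigmoid(b0 + b_ctcf * ctcf_scanned
                      + b_dist * np.log10(distance + 1.0)
                      + b_width * width / 1000.0)
    lost = rng.random(n) < loss_p
    gained = (~lost) & (rng.random(n) < cfg.gain_prob)
    late = rng.random(n) < cfg.late_change_prob
    late_sign = rng.choice([-1.0, 1.0], size=n)

    lo, hi = cfg.accessibility_effect_log2
    effect = rng.uniform(lo, hi, size=n)
    base = np.exp(rng.normal(cfg.peak_mean_log, cfg.peak_mean_log_sd, size=n))

    days = np.repeat(np.asarray(cfg.atac_days), cfg.atac_replicates)
    replicate = np.tile(np.arange(cfg.atac_replicates), len(cfg.atac_days))
    sample_ids = np.array([f"atacP{d}_r{r + 1}"
                           for d, r in zip(days, replicate)], dtype=object)
    size_factors = np.exp(rng.normal(0.0, 0.1, size=days.size))

    level = np.ones((n, len(cfg.atac_days)))
    level[lost, 1:] = 2.0 ** (-effect[lost, None])
    level[gained, 1:] = 2.0 ** (effect[gained, None])
    level[late, 2] = level[late, 1] * 2.0 ** (late_sign[late] * effect[late])
    day_index = {d: k for k, d in enumerate(cfg.atac_days)}
    mean = (base[:, None] * level[:, [day_index[d] for d in days]]
            * size_factors[None, :])
    counts = _nb_draw(rng, mean, cfg.nb_dispersion)

    truth_peaks = pd.DataFrame({
        "name": [iv.name for iv in intervals],
        "start_bp": start, "end_bp": end, "width_bp": width,
        "proximal": proximal, "tss_distance_bp": distance,
        "ctcf_planted": n_ctcf_planted, "ctcf_sites": ctcf_scanned,
        "loss_prob": loss_p,
        "true_class_a_b": np.where(lost, "lost",
                                   np.where(gained, "gained", "stable")),
        "true_late_change": late,
    })
    tss_ann = GeneAnnotation(pd.DataFrame({
        "chromosome": "chrSim",
        "tss_bp": tss,
        "strand": "+",
        "is_tf": False,
        "is_cone_specific": False,
        "pathways": [set() for _ in tss],
    }, index=[f"tssgene{i:05d}" for i in range(tss.size)]))
    return PeakSimulation(genome, intervals, counts, days, replicate,
                          sample_ids, tss_ann, TruthTable(peaks=truth_peaks),
                          motif_library)
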