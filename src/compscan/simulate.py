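"""Synthetic study generator.

Emulates every input the analysis consumes: gene annotation on an X arm
plus an autosomal reference arm, two-sex log2 expression with a
configurable compensated fraction and detection floor, IP/input read
coverage with exon-restricted enrichment on bound genes and promoter-only
autosomal signal, knock-down expression whose effect grows with binding
and shrinks with transcript length, high-affinity sites placed near bound
genes, housekeeping labels, and under-replicated regions.

Ground truth is always emitted alongside the data.  Each generator stage
draws from its own stream derived from the single configured seed, so a
stage re-run in isolation reproduces its output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, GenomeAnnotation, RegionSet
from .config import ConfigError, SimulationConfig
from .expression import ExpressionTable
from .tracks import SignalTrack

_STAGE = {
    "annotation": 1,
    "expression": 2,
    "bound": 3,
    "chip": 4,
    "knockdown": 5,
    "has": 6,
}


def _rng(config: SimulationConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), _STAGE[stage]])


# ---------------------------------------------------------------------------
# Annotation


def _make_exons(rng: np.random.Generator, start: int, end: int, k: int):
    """Partition [start, end) into k exons separated by k-1 introns.

    The first and last segments are exons, so the gene span begins and
    ends in exonic sequence.
    """
    length = end - start
    n_seg = 2 * k - 1
    if k <= 1 or length < n_seg * 2:
        return ((start, end),)
    cuts = np.sort(rng.choice(np.arange(1, length), size=n_seg - 1, replace=False))
    bounds = np.concatenate([[0], cuts, [length]])
    return tuple(
        (start + int(bounds[i]), start + int(bounds[i + 1]))
        for i in range(0, n_seg, 2)
    )


def simulate_annotation(config: SimulationConfig) -> GenomeAnnotation:
    """Place non-overlapping genes with random exon structure on each arm."""
    rng = _rng(config, "annotation")
    ann = GenomeAnnotation(arms=dict(config.arms))
    per_arm = config.genes_per_arm
    for arm, arm_len in config.arms:
        n = per_arm.get(arm, 0) if isinstance(per_arm, dict) else per_arm
        if n == 0:
            continue
        lengths = np.maximum(
            np.round(
                config.gene_length_median
                * np.exp(rng.normal(0.0, config.gene_length_sigma, n))
            ).astype(int),
            300,
        )
        gaps = rng.integers(
            config.min_intergenic_gap, 3 * config.min_intergenic_gap + 1, n
        )
        if lengths.sum() + gaps.sum() > arm_len:
            raise ConfigError(
                f"arm {arm!r} (length {arm_len}) too short for {n} genes "
                f"(needs {int(lengths.sum() + gaps.sum())} bp)"
            )
        strands = np.where(rng.random(n) < 0.5, "+", "-")
        if n >= 2 and len(set(strands)) == 1:
            strands[-1] = "+" if strands[0] == "-" else "-"
        pos = int(gaps[0])
        for i in range(n):
            start, end = pos, pos + int(lengths[i])
            k = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons = _make_exons(rng, start, end, k)
            ann.add(
                GeneModel(f"{arm}g{i + 1:04d}", arm, start, end, str(strands[i]), exons)
            )
            pos = end + int(gaps[i])
    return ann


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    config: SimulationConfig, annotation: GenomeAnnotation
) -> tuple[ExpressionTable, pd.DataFrame]:
    """Two-sex log2 expression plus per-gene ground-truth labels.

    Expressed genes draw a base level above the detection floor; a
    fraction ``unexpressed_fraction`` sits well below it.  Compensated X
    genes have equal male and female means; non-compensated X genes are
    shifted by ``uncompensated_shift`` in males; autosomal genes carry a
    Gaussian sex bias.  Technical noise of SD ``ratio_noise_sd/sqrt(2)``
    is added per sex so the male-female ratio noise has SD
    ``ratio_noise_sd``.
    """
    if len(annotation) == 0:
        raise ConfigError("annotation is empty")
    rng = _rng(config, "expression")
    ids = list(annotation.genes)
    arms = np.array([annotation[g].arm for g in ids])
    n = len(ids)
    mean, sd = config.expression_mean_sd
    floor = config.detection_floor

    expressed = rng.random(n) >= config.unexpressed_fraction
    base = np.empty(n)
    # expressed: truncated normal above the floor
    n_exp = int(expressed.sum())
    draws = rng.normal(mean, sd, n_exp)
    bad = draws < floor
    while bad.any():
        draws[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = draws < floor
    base[expressed] = draws
    base[~expressed] = rng.uniform(2.0, max(floor - 1.0, 2.5), n - n_exp)

    is_x = arms == "X"
    compensated = np.zeros(n, dtype=bool)
    comp_draw = rng.random(n) < config.compensated_fraction_X
    compensated[is_x & expressed] = comp_draw[is_x & expressed]

    bias = np.zeros(n)
    auto_bias = rng.normal(0.0, config.sex_bias_sd, n)
    bias[~is_x & expressed] = auto_bias[~is_x & expressed]
    bias[is_x & expressed & ~compensated] = config.uncompensated_shift

    s = config.ratio_noise_sd / np.sqrt(2.0)
    female = base + (rng.normal(0.0, s, n) if s > 0 else 0.0)
    male = base + bias + (rng.normal(0.0, s, n) if s > 0 else 0.0)

    table = ExpressionTable(
        pd.DataFrame({"male": male, "female": female}, index=pd.Index(ids, name="gene_id")),
        sample_info=pd.DataFrame(
            {"sex": ["male", "female"], "condition": ["wild_type"] * 2},
            index=["male", "female"],
        ),
    )
    truth = pd.DataFrame(
        {
            "arm": arms,
            "expressed": expressed,
            "compensated": compensated,
            "sex_bias": bias,
        },
        index=pd.Index(ids, name="gene_id"),
    )
    return table, truth


def choose_bound_genes(
    config: SimulationConfig, truth: pd.DataFrame
) -> set[str]:
    """Bound genes: a fraction of expressed X genes."""
    rng = _rng(config, "bound")
    candidates = truth.index[(truth["arm"] == "X") & truth["expressed"]]
    pick = rng.random(len(candidates)) < config.bound_fraction_X
    return set(candidates[pick])


# ---------------------------------------------------------------------------
# ChIP coverage


def simulate_chip_tracks(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    bound_genes: set[str],
) -> tuple[SignalTrack, SignalTrack, SignalTrack, pd.Series]:
    """Per-nucleotide Poisson IP and input coverage, plus true fold per gene.

    Bound genes' exons are enriched in the IP by a per-gene fold drawn
    log-uniformly from ``enrichment_range``; autosomal genes carry
    ``promoter_signal_fold`` over a fixed promoter window only.  The male
    input (and the IP, which comes from the same male tissue) reflects
    ``copy_ratio_X`` on the X arm.
    """
    unknown = bound_genes - set(annotation.genes)
    if unknown:
        raise ConfigError(f"bound genes not in annotation: {sorted(unknown)[:3]}")
    rng = _rng(config, "chip")
    ids = list(annotation.genes)
    folds = pd.Series(1.0, index=pd.Index(ids, name="gene_id"), name="true_fold")
    lo, hi = config.enrichment_range
    for gid in ids:
        if gid in bound_genes:
            folds[gid] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    ip_data, im_data, if_data = {}, {}, {}
    pw0, pw1 = config.promoter_window
    for arm, arm_len in config.arms:
        rate_ip = np.ones(arm_len)
        for g in annotation.on_arm(arm):
            if g.gene_id in bound_genes:
                f = folds[g.gene_id]
                for a, b in g.exons:
                    rate_ip[a:b] *= f
            if arm != "X":
                a = max(g.tss + pw0, 0)
                b = min(g.tss + pw1, arm_len)
                if b > a:
                    rate_ip[a:b] *= config.promoter_signal_fold
        cn = config.copy_ratio_X if arm == "X" else 1.0
        ip_data[arm] = rng.poisson(config.read_depth_ip * cn * rate_ip).astype(float)
        im_data[arm] = rng.poisson(
            config.read_depth_input_male * cn, arm_len
        ).astype(float)
        if_data[arm] = rng.poisson(
            config.read_depth_input_female, arm_len
        ).astype(float)
    return (
        SignalTrack(1, ip_data),
        SignalTrack(1, im_data),
        SignalTrack(1, if_data),
        folds,
    )


# ---------------------------------------------------------------------------
# Knock-down expression


def simulate_knockdown(
    config: SimulationConfig,
    expression: ExpressionTable,
    binding_truth: pd.Series,
    annotation: GenomeAnnotation,
    baseline: str = "male",
) -> ExpressionTable:
    """Add 'control' and 'knockdown' columns to the expression table.

    The log2 drop follows the saturating :class:`KnockdownModel`: it
    increases with true binding fold and decreases with transcript length;
    unbound genes (fold 1) drop by 0 in expectation.
    """
    kd = config.knockdown
    rng = _rng(config, "knockdown")
    ids = expression.gene_ids
    folds = binding_truth.reindex(ids).fillna(1.0).to_numpy()
    lengths = np.array([annotation[g].length for g in ids], dtype=float)
    drop = kd.drop(folds, lengths)
    base = expression.data[baseline].to_numpy()
    s = kd.noise_sd / np.sqrt(2.0)
    control = base + (rng.normal(0.0, s, len(ids)) if s > 0 else 0.0)
    knock = base - drop + (rng.normal(0.0, s, len(ids)) if s > 0 else 0.0)
    df = expression.data.copy()
    df["control"] = control
    df["knockdown"] = knock
    info = pd.DataFrame(
        {
            "sex": ["male", "female", "male", "male"],
            "condition": ["wild_type", "wild_type", "mock", "knockdown"],
        },
        index=["male", "female", "control", "knockdown"],
    )
    return ExpressionTable(df, sample_info=info)


# ---------------------------------------------------------------------------
# HAS, labels, regions


def simulate_has_and_labels(
    config: SimulationConfig,
    annotation: GenomeAnnotation,
    bound_genes: set[str],
) -> tuple[RegionSet, dict[str, bool], RegionSet]:
    """High-affinity sites, housekeeping flags and under-replicated regions.

    Sites are placed on the X arm, preferentially near bound genes;
    housekeeping flags are Bernoulli with separate rates for bound and
    unbound genes; under-replicated regions are uniform across arms.
    """
    rng = _rng(config, "has")
    arm_lengths = dict(config.arms)
    has_regions: list[tuple[str, int, int]] = []
    site_w = 300
    x_len = arm_lengths.get("X")
    bound_x = sorted(g for g in bound_genes if annotation[g].arm == "X")
    for _ in range(config.has_count):
        if x_len is None:
            arm = list(arm_lengths)[0]
            center = int(rng.integers(0, arm_lengths[arm]))
            has_regions.append((arm, max(center - site_w // 2, 0),
                                min(center + site_w // 2, arm_lengths[arm])))
            continue
        if bound_x and rng.random() < config.has_near_bound_prob:
            g = annotation[bound_x[int(rng.integers(0, len(bound_x)))]]
            center = int(round(g.start + rng.normal(0.0, config.has_placement_sd)))
        else:
            center = int(rng.integers(0, x_len))
        a = int(np.clip(center - site_w // 2, 0, x_len - site_w))
        has_regions.append(("X", a, a + site_w))
    has = RegionSet("HAS", has_regions)

    housekeeping = {}
    for gid in annotation.genes:
        p = (
            config.housekeeping_fraction_bound
            if gid in bound_genes
            else config.housekeeping_fraction_unbound
        )
        housekeeping[gid] = bool(rng.random() < p)

    ur_regions = []
    arms = list(arm_lengths)
    weights = np.array([arm_lengths[a] for a in arms], dtype=float)
    weights /= weights.sum()
    for _ in range(config.n_under_replicated):
        arm = arms[int(rng.choice(len(arms), p=weights))]
        w = min(config.under_replicated_length, arm_lengths[arm])
        a = int(rng.integers(0, arm_lengths[arm] - w + 1))
        ur_regions.append((arm, a, a + w))
    under_replicated = RegionSet("under_replicated", ur_regions)
    return has, housekeeping, under_replicated


# ---------------------------------------------------------------------------
# Bundle


@dataclass
class SimulatedStudy:
    """Everything one synthetic study produces, ground truth included."""

    config: SimulationConfig
    annotation: GenomeAnnotation
    expression: ExpressionTable
    truth: pd.DataFrame
    bound_genes: set[str]
    ip: SignalTrack
    input_male: SignalTrack
    input_female: SignalTrack
    true_folds: pd.Series
    has: RegionSet
    housekeeping: dict[str, bool]
    under_replicated: RegionSet


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Run all generator stages with one seed."""
    ann = simulate_annotation(config)
    expr, truth = simulate_expression(config, ann)
    bound = choose_bound_genes(config, truth)
    ip, im, iff, folds = simulate_chip_tracks(config, ann, bound)
    expr_kd = simulate_knockdown(config, expr, folds, ann)
    has, hk, ur = simulate_has_and_labels(config, ann, bound)
    return SimulatedStudy(
        config=config,
        annotation=ann,
        expression=expr_kd,
        truth=truth,
        bound_genes=bound,
        ip=ip,
        input_male=im,
        input_female=iff,
        true_folds=folds,
        has=has,
        housekeeping=hk,
        under_replicated=ur,
    )
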