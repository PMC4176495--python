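"""Configuration dataclasses for the simulator and the ChIP pipeline.

All analysis thresholds live in :class:`EnrichmentParams` and mirror the
published procedure: 10 bp first-pass median smoothing on a 10 bp grid, an
input floor of 4 reads, 200 bp second-pass smoothing discarding windows
with fewer than 10 points, a 200 bp 5' exonic exclusion, and per-gene
binding values as the mean of the top 50% of exonic grid values (genes
with fewer than 10 points are unqualified).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from typing import Any


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class EnrichmentParams:
    """Parameters of the IP/input enrichment and gene-binding pipeline."""

    smooth1_window: int = 10
    grid_step: int = 10
    input_floor_min: float = 4.0
    smooth2_window: int = 200
    min_points_per_window: int = 10
    exclude_first_exonic_bp: int = 200
    top_fraction: float = 0.5
    min_points_per_gene: int = 10
    copy_smooth_window: int = 1000
    strand_aware_exclusion: bool = True

    def __post_init__(self) -> None:
        for name in ("smooth1_window", "grid_step", "smooth2_window", "copy_smooth_window"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if not (0 < self.top_fraction <= 1):
            raise ConfigError("top_fraction must be in (0, 1]")
        if self.exclude_first_exonic_bp < 0:
            raise ConfigError("exclude_first_exonic_bp must be >= 0")
        if self.min_points_per_window < 1 or self.min_points_per_gene < 1:
            raise ConfigError("min-point thresholds must be >= 1")


@dataclass
class KnockdownModel:
    """Saturating response of expression to MSL/MOF loss.

    log2 drop = max_drop * (f - 1) / (f - 1 + half_saturation)
                * length_scale / (length_scale + length)
    for true fold enrichment ``f``; the drop is clamped so residual
    expression never falls below ``residual_floor`` of wild-type.  Defaults
    put a strongly bound short gene at roughly 80% residual expression.
    """

    max_drop: float = 0.4
    half_saturation: float = 15.0
    length_scale: float = 20000.0
    noise_sd: float = 0.1
    residual_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.max_drop < 0 or self.noise_sd < 0:
            raise ConfigError("max_drop and noise_sd must be >= 0")
        if self.half_saturation <= 0 or self.length_scale <= 0:
            raise ConfigError("half_saturation and length_scale must be positive")
        if not (0 < self.residual_floor <= 1):
            raise ConfigError("residual_floor must be in (0, 1]")

    def drop(self, fold, length):
        """Expected log2 expression drop (no noise)."""
        import numpy as np

        fold = np.asarray(fold, dtype=float)
        length = np.asarray(length, dtype=float)
        sat = (fold - 1.0) / (fold - 1.0 + self.half_saturation)
        att = self.length_scale / (self.length_scale + length)
        d = self.max_drop * np.clip(sat, 0.0, None) * att
        return np.minimum(d, -np.log2(self.residual_floor))


@dataclass
class SimulationConfig:
    """Full description of one synthetic study.

    The defaults describe the study conditions the analysis assumes: an X
    arm plus an autosomal reference arm, a ~2-fold male deficit for
    non-compensated X genes, a log2 detection floor of 6, exon-restricted
    MSL-type enrichment on bound X genes, promoter-only autosomal signal,
    and a knock-down response saturating near 80% residual expression.
    """

    seed: int = 0
    arms: list[tuple[str, int]] = field(
        default_factory=lambda: [("X", 2_500_000), ("3L", 2_500_000)]
    )
    genes_per_arm: int | dict[str, int] = 300  # one count, or per-arm counts
    gene_length_median: float = 3000.0
    gene_length_sigma: float = 1.1  # sigma of log length
    exons_per_gene: tuple[int, int] = (1, 6)
    min_intergenic_gap: int = 200
    compensated_fraction_X: float = 0.9
    uncompensated_shift: float = -1.0
    expression_mean_sd: tuple[float, float] = (8.5, 1.2)
    unexpressed_fraction: float = 0.2
    detection_floor: float = 6.0
    ratio_noise_sd: float = 0.2
    sex_bias_sd: float = 0.45
    bound_fraction_X: float = 0.6
    enrichment_range: tuple[float, float] = (2.0, 64.0)
    promoter_signal_fold: float = 4.0
    promoter_window: tuple[int, int] = (-200, 200)  # relative to the TSS
    read_depth_ip: float = 10.0
    read_depth_input_male: float = 10.0
    read_depth_input_female: float = 10.0
    copy_ratio_X: float = 1.0
    knockdown: KnockdownModel = field(default_factory=KnockdownModel)
    has_count: int = 50
    has_near_bound_prob: float = 0.8
    has_placement_sd: float = 5000.0
    housekeeping_fraction_bound: float = 0.7
    housekeeping_fraction_unbound: float = 0.3
    n_under_replicated: int = 10
    under_replicated_length: int = 50_000

    def __post_init__(self) -> None:
        for name in (
            "compensated_fraction_X",
            "unexpressed_fraction",
            "bound_fraction_X",
            "housekeeping_fraction_bound",
            "housekeeping_fraction_unbound",
            "has_near_bound_prob",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        for arm, length in self.arms:
            if length <= 0:
                raise ConfigError(f"arm {arm} has non-positive length {length}")
        counts = (
            self.genes_per_arm.values()
            if isinstance(self.genes_per_arm, dict)
            else [self.genes_per_arm]
        )
        if any(c < 0 for c in counts):
            raise ConfigError("genes_per_arm must be >= 0")
        lo, hi = self.enrichment_range
        if lo < 1.0 or hi < lo:
            raise ConfigError("enrichment_range folds must be >= 1 and ordered")
        if self.promoter_signal_fold < 1.0:
            raise ConfigError("promoter_signal_fold must be >= 1")
        for name in ("read_depth_ip", "read_depth_input_male", "read_depth_input_female"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.copy_ratio_X <= 0:
            raise ConfigError("copy_ratio_X must be positive")
        if self.ratio_noise_sd < 0 or self.sex_bias_sd < 0:
            raise ConfigError("noise SDs must be >= 0")
        if self.exons_per_gene[0] < 1 or self.exons_per_gene[1] < self.exons_per_gene[0]:
            raise ConfigError("exons_per_gene range must be >= 1 and ordered")
        if isinstance(self.knockdown, dict):
            self.knockdown = KnockdownModel(**self.knockdown)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


_KNOWN_TOP_KEYS = {
    "simulation",
    "enrichment",
    "expression_threshold",
    "reference_arm",
    "length_threshold",
    "seed",
    "outdir",
    "simulate",
    "annotation",
    "expression",
    "ip_track",
    "input_male_track",
    "input_female_track",
    "has",
    "under_replicated",
    "housekeeping",
    "normalize_input_depth",
}


def validate_config(raw: dict[str, Any] | None) -> tuple[dict[str, Any], list[str]]:
    """Fill defaults into a raw (YAML-derived) config; warn on unknown keys.

    Returns the validated config dict and a list of warning strings.
    Type or range violations raise :class:`ConfigError`.
    """
    raw = dict(raw or {})
    warnings: list[str] = []
    for key in sorted(set(raw) - _KNOWN_TOP_KEYS):
        warnings.append(f"unknown config key {key!r} ignored")
        raw.pop(key)

    sim_in = raw.get("simulation")
    if isinstance(sim_in, SimulationConfig):  # already validated upstream
        sim_in = sim_in.to_dict()
    sim_raw = dict(sim_in or {})
    sim_field_names = {f.name for f in fields(SimulationConfig)}
    for key in sorted(set(sim_raw) - sim_field_names):
        warnings.append(f"unknown simulation key {key!r} ignored")
        sim_raw.pop(key)
    if "arms" in sim_raw:
        sim_raw["arms"] = [(str(a), int(b)) for a, b in sim_raw["arms"]]
    if "seed" in raw and "seed" not in sim_raw:
        sim_raw["seed"] = int(raw["seed"])
    try:
        sim = SimulationConfig(**sim_raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc

    enr_in = raw.get("enrichment")
    if isinstance(enr_in, EnrichmentParams):
        enr_in = {f.name: getattr(enr_in, f.name) for f in fields(EnrichmentParams)}
    enr_raw = dict(enr_in or {})
    enr_field_names = {f.name for f in fields(EnrichmentParams)}
    for key in sorted(set(enr_raw) - enr_field_names):
        warnings.append(f"unknown enrichment key {key!r} ignored")
        enr_raw.pop(key)
    try:
        enr = EnrichmentParams(**enr_raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc

    out = dict(raw)
    out["simulation"] = sim
    out["enrichment"] = enr
    out.setdefault("expression_threshold", 6.0)
    out.setdefault("reference_arm", "3L")
    out.setdefault("length_threshold", 10_000)
    out.setdefault("seed", sim.seed)
    out.setdefault("simulate", True)
    out.setdefault("normalize_input_depth", True)
    if not isinstance(out["expression_threshold"], (int, float)):
        raise ConfigError("expression_threshold must be numeric")
    if out["length_threshold"] <= 0:
        raise ConfigError("length_threshold must be positive")
    return out, warnings


def load_config(path: str) -> tuple[dict[str, Any], list[str]]:
    """Load a YAML config file and validate it."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")
    return validate_config(raw)
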