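"""Microsatellite panel (BED) and pipeline configuration handling.

The panel is a plain BED3+ file: one microsatellite tract per record,
0-based half-open coordinates, optional name in column 4. The pipeline
configuration is a flat key/value YAML file whose defaults encode the
read- and region-level filters of the screening method (mapping quality
>= 20, 5 bp flanks, 30x minimum depth, singleton cleaning, 75% coverage
requirement, per-locus AUC floor of 0.60).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "MsLocus",
    "ThresholdConfig",
    "PipelineConfig",
    "PanelError",
    "ConfigError",
    "parse_panel",
    "write_panel",
    "load_config",
    "config_to_dict",
    "config_from_dict",
]


class PanelError(ValueError):
    """Malformed or inconsistent panel definition."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass(frozen=True)
class MsLocus:
    """One microsatellite target region (0-based half-open coordinates)."""

    name: str
    chrom: str
    start: int
    end: int
    source: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise PanelError(
                f"locus {self.name!r}: end <= start ({self.end} <= {self.start})"
            )
        if self.start < 0:
            raise PanelError(f"locus {self.name!r}: negative start")

    @property
    def ref_length(self) -> int:
        """Reference tract length in bases (end - start)."""
        return self.end - self.start

    def flanked_interval(self, flank: int) -> tuple[int, int]:
        """Interval including ``flank`` bases on each side; must not underflow 0."""
        lo = self.start - flank
        if lo < 0:
            raise PanelError(
                f"locus {self.name!r}: flank of {flank} underflows position 0"
            )
        return lo, self.end + flank


@dataclass(frozen=True)
class ThresholdConfig:
    """Sample-score classification thresholds.

    ``binary`` mode calls MSI iff score > binary_cutoff (strict). ``dual``
    mode keeps a gray zone: MSS below ``low``, MSI above ``high``, GRAY in
    between (rule-out / rule-in cutoffs each chosen for 95% specificity).
    """

    mode: str = "binary"
    low: float = 0.10
    high: float = 0.26
    binary_cutoff: float = 0.26

    def __post_init__(self) -> None:
        if self.mode not in ("binary", "dual"):
            raise ConfigError(f"threshold mode must be 'binary' or 'dual', got {self.mode!r}")
        for key in ("low", "high", "binary_cutoff"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"threshold {key}={v} outside [0, 1]")
        if self.low > self.high:
            raise ConfigError(f"threshold low={self.low} > high={self.high}")


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable parameters of the screening pipeline.

    Defaults are the method's published operating point: reads need MAPQ
    >= 20 and must span the tract plus 5 bp flanks; a locus is evaluable
    at >= 30x depth after removing singleton lengths; loci must be
    evaluable in >= 75% of training samples and reach validation AUC
    >= 0.60 in both models to stay in the panel.
    """

    flank_bases: int = 5
    min_mapq: int = 20
    min_depth: int = 30
    singleton_cutoff: int = 1
    coverage_fraction: float = 0.75
    locus_auc_min: float = 0.60
    window: int = 20
    kfold: int = 3
    min_evaluable_loci: Optional[int] = None
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("flank_bases", "min_mapq", "min_depth", "singleton_cutoff",
                    "window", "kfold", "seed"):
            v = getattr(self, key)
            if not isinstance(v, int) or v < 0:
                raise ConfigError(f"{key}={v!r} must be a nonnegative integer")
        if self.kfold < 2:
            raise ConfigError(f"kfold={self.kfold} must be >= 2")
        if not 0.0 < self.coverage_fraction <= 1.0:
            raise ConfigError(
                f"coverage_fraction={self.coverage_fraction} outside (0, 1]"
            )
        if not 0.5 <= self.locus_auc_min < 1.0:
            raise ConfigError(f"locus_auc_min={self.locus_auc_min} outside [0.5, 1)")
        if self.min_evaluable_loci is not None and (
            not isinstance(self.min_evaluable_loci, int) or self.min_evaluable_loci < 1
        ):
            raise ConfigError("min_evaluable_loci must be a positive integer or null")

    @property
    def vector_length(self) -> int:
        return 2 * self.window + 1


def parse_panel(path: str | Path) -> list[MsLocus]:
    """Parse a BED3+ panel file into a list of loci, preserving file order.

    Column 4, when present, is the locus name; otherwise names are
    auto-generated as ``chrom_start_end``. Column 5+ is ignored except that
    column 5, when non-numeric, is kept as a free-text ``source`` tag.
    """
    path = Path(path)
    loci: list[MsLocus] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PanelError(
                    f"{path.name} line {lineno}: expected >= 3 tab-separated columns"
                )
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise PanelError(
                    f"{path.name} line {lineno}: non-integer coordinates"
                ) from exc
            if end <= start:
                raise PanelError(f"{path.name} line {lineno}: end <= start")
            name = parts[3] if len(parts) > 3 and parts[3].strip() else f"{chrom}_{start}_{end}"
            source = None
            if len(parts) > 4 and parts[4].strip():
                try:
                    float(parts[4])  # BED score column: not a source tag
                except ValueError:
                    source = parts[4]
            if name in seen:
                raise PanelError(f"{path.name} line {lineno}: duplicate locus name {name!r}")
            seen.add(name)
            loci.append(MsLocus(name=name, chrom=chrom, start=start, end=end, source=source))
    return loci


def write_panel(loci: list[MsLocus], path: str | Path) -> None:
    """Write loci back to BED (inverse of :func:`parse_panel`)."""
    with open(path, "w") as fh:
        for loc in loci:
            cols = [loc.chrom, str(loc.start), str(loc.end), loc.name]
            if loc.source is not None:
                cols.append(loc.source)
            fh.write("\t".join(cols) + "\n")


_THRESHOLD_KEYS = {
    "threshold_mode": "mode",
    "threshold_low": "low",
    "threshold_high": "high",
    "binary_cutoff": "binary_cutoff",
}


def load_config(path: str | Path) -> PipelineConfig:
    """Load a flat key/value YAML config; unknown keys are rejected."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: config must be a flat key/value mapping")
    return config_from_dict(data)


def config_from_dict(data: dict) -> PipelineConfig:
    plain = {f.name for f in dataclasses.fields(PipelineConfig)} - {"thresholds"}
    kwargs: dict = {}
    thr_kwargs: dict = {}
    for key, value in data.items():
        if key in plain:
            kwargs[key] = value
        elif key in _THRESHOLD_KEYS:
            thr_kwargs[_THRESHOLD_KEYS[key]] = value
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    if thr_kwargs:
        kwargs["thresholds"] = ThresholdConfig(**thr_kwargs)
    return PipelineConfig(**kwargs)


def config_to_dict(config: PipelineConfig) -> dict:
    """Flat key/value form of a config (inverse of :func:`config_from_dict`)."""
    out = {
        f.name: getattr(config, f.name)
        for f in dataclasses.fields(PipelineConfig)
        if f.name != "thresholds"
    }
    thr = config.thresholds
    out.update(
        threshold_mode=thr.mode,
        threshold_low=thr.low,
        threshold_high=thr.high,
        binary_cutoff=thr.binary_cutoff,
    )
    return out
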