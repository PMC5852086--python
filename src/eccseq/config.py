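"""Detection thresholds and sample constants.

Every cutoff the pipeline applies lives in :class:`DetectionConfig`, so a run
is fully described by one config object (serialisable to/from YAML).  The
defaults are the operating point of the Circle-Seq detection scheme this
package implements: two independent structural-read variants per call, a
50-base minimum soft clip, a 1 Mb ceiling on circle size, the 95% coverage /
2-fold flank rules for confidence ranking, and the reciprocal-overlap
fractions used for merging (50%), cross-sample recurrence (90%) and
variant-database intersection (99%).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable

import yaml

__all__ = [
    "DetectionConfig",
    "SpikeInControl",
    "DEFAULT_SPIKE_INVENTORY",
    "load_config",
    "dump_config",
]


@dataclass
class DetectionConfig:
    """All tunable thresholds of the detection pipeline.

    Attributes
    ----------
    min_softclip_bases:
        Minimum number of soft-clipped bases for a read to count as junction
        evidence (and for its clipped fragment to be realigned).
    min_structural_variants:
        Minimum number of independent structural-read variants (distinct
        reads) required to emit a circle call.
    max_circle_size:
        Circles larger than this (bp) are never called.
    coverage_fraction_threshold:
        Fraction of internal positions that must have depth >= 1 for a call
        to rise above ``lowq``.
    coverage_fold_threshold:
        ``hconf`` additionally requires mean internal coverage greater than
        this multiple of the flank coverage statistic.
    flank_mode:
        ``"sum"`` compares mean coverage against the *sum* of the upstream and
        downstream flank means (the default reading); ``"mean"`` compares
        against their average.
    merge_reciprocal_overlap:
        Calls with reciprocal overlap at or above this fraction collapse into
        one record.
    recurrence_reciprocal_overlap:
        Reciprocal overlap required to count the same circle across samples.
    variantdb_reciprocal_overlap:
        Reciprocal overlap for intersection with an external variant database.
    rna_max_start_deviation:
        Maximum distance (nt) between a split-transcript read's implied start
        and the circle start for the read to support transcription.
    mc_randomizations:
        Number of genome randomizations for the Monte Carlo nulls.
    cluster_tolerance_bp:
        Matching tolerance for *inexact* junction hints during evidence
        clustering (about one sequencing insert size).
    exact_tolerance_bp:
        Matching tolerance for exact junction coordinates during clustering.
    realign_kmer:
        Seed k-mer length for clipped-fragment realignment.
    realign_min_identity:
        Minimum ungapped identity for an accepted realignment.
    min_mapq:
        Mapping-quality floor for evidence reads.
    decimation_step:
        Step of the read-decimation (saturation) curve.
    length_correction:
        Whether spike-in quantification corrects for template length
        (reads scale with template mass, not copy number).
    use_duplicates / use_secondary:
        Whether duplicate-marked / secondary alignments contribute to
        evidence and coverage (both off by default).
    seed:
        Seed for every source of randomness.
    """

    min_softclip_bases: int = 50
    min_structural_variants: int = 2
    max_circle_size: int = 1_000_000
    coverage_fraction_threshold: float = 0.95
    coverage_fold_threshold: float = 2.0
    flank_mode: str = "sum"
    merge_reciprocal_overlap: float = 0.50
    recurrence_reciprocal_overlap: float = 0.90
    variantdb_reciprocal_overlap: float = 0.99
    rna_max_start_deviation: int = 20
    mc_randomizations: int = 1_000
    cluster_tolerance_bp: int = 500
    exact_tolerance_bp: int = 5
    realign_kmer: int = 15
    realign_min_identity: float = 0.95
    min_mapq: int = 1
    decimation_step: float = 0.10
    length_correction: bool = True
    use_duplicates: bool = False
    use_secondary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_softclip_bases <= 0 or self.min_structural_variants <= 0:
            raise ValueError("thresholds must be positive")
        if self.max_circle_size <= 0 or self.cluster_tolerance_bp <= 0:
            raise ValueError("thresholds must be positive")
        for name in (
            "coverage_fraction_threshold",
            "merge_reciprocal_overlap",
            "recurrence_reciprocal_overlap",
            "variantdb_reciprocal_overlap",
            "realign_min_identity",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.flank_mode not in ("sum", "mean"):
            raise ValueError("flank_mode must be 'sum' or 'mean'")
        if self.mc_randomizations < 1:
            raise ValueError("mc_randomizations must be >= 1")

    def replace(self, **kwargs) -> "DetectionConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class SpikeInControl:
    """One spike-in plasmid added to a sample at a known copy number."""

    name: str
    length_bp: int
    copies_added: int
    nuclei_in_sample: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.length_bp, self.copies_added, self.nuclei_in_sample) <= 0:
            raise ValueError("spike-in fields must be positive")


def default_spike_inventory(nuclei_in_sample: int = 1_000_000) -> list[SpikeInControl]:
    """The five-plasmid control mixture added to every sample."""
    inv = [
        ("pSH63", 6_998, 100),
        ("pUC19_yEGFP3", 3_397, 100),
        ("YGPM3k20", 26_305, 10_000),
        ("pBR322", 4_361, 20_000),
        ("pUG72", 3_988, 50_000),
    ]
    return [
        SpikeInControl(name, length, copies, nuclei_in_sample)
        for name, length, copies in inv
    ]


DEFAULT_SPIKE_INVENTORY = default_spike_inventory()


def load_config(path: str, **overrides) -> DetectionConfig:
    """Load a :class:`DetectionConfig` from a YAML file (flat key: value)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config file {path!r} must hold a mapping")
    known = {f.name for f in dataclasses.fields(DetectionConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    return DetectionConfig(**data)


def dump_config(cfg: DetectionConfig, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_header_lines(cfg: DetectionConfig) -> Iterable[str]:
    """Config snapshot as '#'-prefixed lines embedded in output tables."""
    for key, value in sorted(cfg.to_dict().items()):
        yield f"# {key}={value}"
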