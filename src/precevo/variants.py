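"""Multi-caller somatic variant harmonization.

Calls from three callers (labelled M2, SC, MU) are combined by a two-or-more
vote; when MU is unavailable the union of M2 and SC is used instead.  The
consensus set is complemented by a targeted rescue of single-caller calls at
driver hotspots and at sites already found by the stringent rule elsewhere in
the same patient.  Downstream filters: population allele frequency,
indel depth, deleteriousness classification, and mutation burden.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from importlib import resources as _importlib_resources
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Variant",
    "RescuePanel",
    "CALLERS",
    "PREDICTORS",
    "consensus_calls",
    "population_filter",
    "rescue_targeted",
    "classify_deleterious",
    "filter_indels",
    "mutation_burden",
    "load_driver_loci",
]

CALLERS = ("M2", "SC", "MU")
#: depth/VAF precedence when callers disagree on a shared variant
MERGE_PRECEDENCE = ("M2", "MU", "SC")
PREDICTORS = ("sift", "polyphen", "HVAR", "LRT", "mutationTaster", "fathmm", "provean")

VariantKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class Variant:
    """One somatic SNV/indel call with its annotations.

    ``predictor_verdicts`` is a 7-tuple of booleans ordered as
    :data:`PREDICTORS`.  ``pop_af`` is the maximum population allele
    frequency, ``None`` when the site is absent from population databases.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str = "SNV"  # "SNV" or "indel"
    tumor_depth: int = 0
    tumor_alt: int = 0
    normal_depth: int | None = None
    normal_alt: int | None = None
    callers: frozenset = frozenset()
    quality: float = 0.0
    pop_af: float | None = None
    predictor_verdicts: tuple = (False,) * 7
    clinvar: str = "absent"  # pathogenic / other / absent
    func_class: str = "exonic"  # exonic / splicing / other
    gene: str | None = None
    rescued: bool = False

    def __post_init__(self):
        if self.tumor_alt > self.tumor_depth:
            raise ValueError("tumor_alt exceeds tumor_depth")
        if self.clinvar not in ("pathogenic", "other", "absent"):
            raise ValueError(f"bad clinvar value {self.clinvar!r}")
        if self.func_class not in ("exonic", "splicing", "other"):
            raise ValueError(f"bad func_class {self.func_class!r}")
        if len(self.predictor_verdicts) != len(PREDICTORS):
            raise ValueError("predictor_verdicts must have 7 entries")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def site(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    @property
    def vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth else 0.0


@dataclass
class RescuePanel:
    """Targeted-rescue configuration.

    ``driver_loci``: predetermined (chrom, pos) hotspot sites in established
    driver genes.  ``shared_sites``: per-patient sites already detected by the
    stringent rule in another non-blood sample of the same patient.
    ``relaxed_threshold``: minimum caller quality (emission log-odds) for a
    rescued call.
    """

    driver_loci: set = field(default_factory=set)
    shared_sites: set = field(default_factory=set)
    relaxed_threshold: float = 1.5

    def __post_init__(self):
        if not self.driver_loci:
            raise ValueError("driver_loci must be nonempty when rescue is enabled")


def load_driver_loci(path=None) -> dict[tuple[str, int], str]:
    """Packaged driver hotspot sites: {(chrom, pos): gene} (toy coordinates)."""
    src = path if path is not None else (
        _importlib_resources.files("precevo.resources") / "driver_loci_toy.tsv"
    )
    out: dict[tuple[str, int], str] = {}
    with open(src) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out[(str(row["chrom"]), int(row["pos"]))] = row["gene"]
    return out


def _merge(group: Sequence[Variant]) -> Variant:
    """Merge the same variant as seen by several callers (M2 > MU > SC)."""
    by_caller = {next(iter(v.callers)): v for v in group}
    order = [c for c in MERGE_PRECEDENCE if c in by_caller]
    primary = by_caller[order[0]]
    all_callers = frozenset().union(*(v.callers for v in group))
    return replace(primary, callers=all_callers)


def consensus_calls(
    per_caller_sets: Mapping[str, Iterable[Variant]],
    available_callers: Sequence[str] | None = None,
) -> list[Variant]:
    """Two-or-more vote across three callers; M2 ∪ SC when MU is unavailable.

    Each input variant must carry exactly its own caller in ``callers``;
    output variants carry the full supporting caller subset.
    """
    if available_callers is None:
        available_callers = tuple(per_caller_sets)
    available = [c for c in CALLERS if c in available_callers]
    if len(available) < 2:
        raise ValueError("insufficient callers: need at least 2")

    by_key: dict[VariantKey, list[Variant]] = {}
    for caller in available:
        for v in per_caller_sets.get(caller, []):
            if v.callers != frozenset({caller}):
                v = replace(v, callers=frozenset({caller}))
            by_key.setdefault(v.key, []).append(v)

    union_mode = "MU" not in available
    out = []
    for key in sorted(by_key):
        group = by_key[key]
        n_callers = len({next(iter(v.callers)) for v in group})
        if union_mode or n_callers >= 2:
            out.append(_merge(group))
    return out


def single_caller_calls(
    per_caller_sets: Mapping[str, Iterable[Variant]],
    available_callers: Sequence[str] | None = None,
) -> list[Variant]:
    """Variants seen by exactly one of the available callers (rescue candidates)."""
    if available_callers is None:
        available_callers = tuple(per_caller_sets)
    by_key: dict[VariantKey, list[Variant]] = {}
    for caller in available_callers:
        for v in per_caller_sets.get(caller, []):
            if v.callers != frozenset({caller}):
                v = replace(v, callers=frozenset({caller}))
            by_key.setdefault(v.key, []).append(v)
    return [g[0] for k, g in sorted(by_key.items()) if len(g) == 1]


def population_filter(variants: Iterable[Variant], max_af: float = 0.01) -> list[Variant]:
    """Drop variants with population allele frequency above ``max_af`` (default 1%).

    Variants with no population record are retained.  Idempotent.
    """
    if not 0 < max_af <= 1:
        raise ValueError("max_af must be in (0, 1]")
    return [v for v in variants if v.pop_af is None or v.pop_af <= max_af]


def rescue_targeted(
    single_callers: Iterable[Variant],
    panel: RescuePanel,
    consensus: Iterable[Variant] = (),
) -> list[Variant]:
    """Rescue single-caller calls at panel sites meeting the relaxed threshold.

    The result is site-disjoint from ``consensus`` and flagged ``rescued``.
    """
    consensus_sites = {v.site for v in consensus}
    allowed = panel.driver_loci | panel.shared_sites
    out = []
    for v in single_callers:
        if v.site in consensus_sites:
            continue
        if v.site in allowed and v.quality >= panel.relaxed_threshold:
            out.append(replace(v, rescued=True))
    return out


def classify_deleterious(v: Variant) -> bool:
    """Exonic/splicing AND (>= 2 of 7 predictor verdicts OR ClinVar pathogenic)."""
    if v.func_class not in ("exonic", "splicing"):
        return False
    return sum(bool(x) for x in v.predictor_verdicts) >= 2 or v.clinvar == "pathogenic"


def filter_indels(
    indels: Iterable[Variant], min_tumor: int = 5, max_normal: int = 0
) -> list[Variant]:
    """Keep indels with >= ``min_tumor`` tumor alt reads and <= ``max_normal`` normal alt reads."""
    if min_tumor < 0 or max_normal < 0:
        raise ValueError("read-count thresholds must be nonnegative")
    out = []
    for v in indels:
        if v.tumor_alt < min_tumor:
            continue
        if (v.normal_alt or 0) > max_normal:
            continue
        out.append(v)
    return out


def mutation_burden(
    variants: Iterable[Variant],
    captured_mb: float,
    include_rescued: bool = False,
) -> float:
    """Nonsynonymous mutations per megabase of captured sequence.

    Counts exonic/splicing variants; rescued calls are excluded by default.
    """
    if captured_mb <= 0:
        raise ValueError("captured_mb must be positive")
    n = sum(
        1
        for v in variants
        if v.func_class in ("exonic", "splicing") and (include_rescued or not v.rescued)
    )
    return n / captured_mb
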