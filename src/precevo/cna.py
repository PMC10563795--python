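"""Copy-number calling by overlay of allelic-imbalance and log-ratio segmentations.

A CNA is emitted only where an allelic-imbalance (AI) segment exists; the
direction (gain / loss / copy-neutral LOH) is read off the mean log2 ratio of
the overlapping log-ratio segments.  Arm-level summaries (aneuploidy score,
arm-amplification flags) use a 75%-of-arm base-coverage rule computed on the
union of event bases per arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Segment",
    "CnaEvent",
    "ArmTable",
    "CIN_GENES",
    "FOCAL_MB",
    "ARM_COVERAGE_FRACTION",
    "overlay_cna",
    "classify_focal",
    "aneuploidy_score",
    "arm_amplification_flag",
    "annotate_genes",
]

#: events strictly smaller than this many Mb are "focal"
FOCAL_MB = 3.0
#: fraction of an arm that must be covered by CNA bases for the arm to count
ARM_COVERAGE_FRACTION = 0.75

#: chromosomal-instability gene panel used by :func:`annotate_genes`
CIN_GENES = frozenset(
    {"PARP1", "TP53", "XRCC2", "ATR", "ATM", "MDM2", "RAD51", "CHEK2", "PALB2"}
)

GAIN, LOSS, CNLOH = "gain", "loss", "cnloh"
DIRECTIONS = (GAIN, LOSS, CNLOH)


@dataclass(frozen=True, order=True)
class Segment:
    """One segment of evidence: AI posterior or mean log2 copy ratio.

    Coordinates are 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    kind: str  # "AI" or "LOGR"
    value: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")
        if self.kind not in ("AI", "LOGR"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class CnaEvent:
    """A called copy-number event (1-based inclusive interval)."""

    chrom: str
    start: int
    end: int
    direction: str  # gain / loss / cnloh
    ai_posterior: float = float("nan")
    mean_log2: float = float("nan")

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.start > self.end:
            raise ValueError("event start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def length_mb(self) -> float:
        return self.length / 1e6

    @property
    def focal(self) -> bool:
        return self.length_mb < FOCAL_MB

    def arms_touched(self, arms: "ArmTable") -> list[tuple[str, float]]:
        """Arms intersected by this event with the fraction of each arm covered."""
        out = []
        for row in arms.rows_for_chrom(self.chrom):
            ov = _overlap_len(self.start, self.end, row.start, row.end)
            if ov > 0:
                out.append((f"{row.chrom}{row.arm}", ov / (row.end - row.start + 1)))
        return out


class ArmTable:
    """Chromosome-arm coordinate table (chrom, arm, start, end; 1-based inclusive)."""

    def __init__(self, df: pd.DataFrame):
        required = {"chrom", "arm", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"arm table needs columns {sorted(required)}")
        df = df.copy()
        df["chrom"] = df["chrom"].astype(str)
        df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
        for chrom, sub in df.groupby("chrom"):
            ends = sub["end"].to_numpy()
            starts = sub["start"].to_numpy()
            if (starts[1:] <= ends[:-1]).any():
                raise ValueError(f"overlapping arms on chromosome {chrom}")
        self.df = df

    @classmethod
    def from_tsv(cls, path) -> "ArmTable":
        return cls(pd.read_csv(path, sep="\t"))

    @classmethod
    def toy(cls) -> "ArmTable":
        return cls.from_tsv(_resource("arms_toy.tsv"))

    @classmethod
    def hg19(cls) -> "ArmTable":
        return cls.from_tsv(_resource("arms_hg19.tsv"))

    def __iter__(self):
        return iter(self.df.itertuples(index=False))

    def rows_for_chrom(self, chrom: str):
        return [r for r in self if r.chrom == str(chrom)]

    @property
    def arm_ids(self) -> list[str]:
        return [f"{r.chrom}{r.arm}" for r in self]

    def interval(self, arm_id: str) -> tuple[str, int, int]:
        """(chrom, start, end) of an arm id such as ``"1q"``."""
        for r in self:
            if f"{r.chrom}{r.arm}" == arm_id:
                return r.chrom, int(r.start), int(r.end)
        raise KeyError(f"unknown arm {arm_id!r}")

    def length(self, arm_id: str) -> int:
        _, s, e = self.interval(arm_id)
        return e - s + 1

    def genome_size(self) -> int:
        return int((self.df["end"] - self.df["start"] + 1).sum())

    def contains(self, chrom: str, start: int, end: int) -> bool:
        cov = _interval_union_len(
            [(r.start, r.end) for r in self.rows_for_chrom(chrom)], start, end
        )
        return cov == end - start + 1


def _resource(name: str):
    return _importlib_resources.files("precevo.resources") / name


def _overlap_len(s1: int, e1: int, s2: int, e2: int) -> int:
    return max(0, min(e1, e2) - max(s1, s2) + 1)


def _interval_union_len(intervals: Sequence[tuple[int, int]], lo: int, hi: int) -> int:
    """Total bases of ``[lo, hi]`` covered by the union of ``intervals``."""
    clipped = sorted(
        (max(s, lo), min(e, hi)) for s, e in intervals if s <= hi and e >= lo
    )
    total = 0
    cur_s = cur_e = None
    for s, e in clipped:
        if cur_e is None:
            cur_s, cur_e = s, e
        elif s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return total


def _check_segments(segments: Sequence[Segment], kind: str) -> list[Segment]:
    segs = sorted(segments, key=lambda s: (s.chrom, s.start))
    for a, b in zip(segs, segs[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ValueError(f"overlapping {kind} segments at {a.chrom}:{b.start}")
    return segs


def overlay_cna(
    ai: Sequence[Segment],
    logr: Sequence[Segment],
    logr_gain: float = 0.2,
    logr_loss: float = -0.2,
) -> list[CnaEvent]:
    """Call CNA events by overlaying AI segments with log-ratio segments.

    For every AI segment, its intersection with each log-ratio segment is
    classified as gain (mean log2 >= ``logr_gain``), loss (<= ``logr_loss``)
    or cn-LOH (in between).  Touching pieces with the same direction are
    merged.  No event is emitted outside AI territory.
    """
    if logr_loss >= logr_gain:
        raise ValueError("logr_loss must be below logr_gain")
    ai_segs = _check_segments(ai, "AI")
    logr_segs = _check_segments(logr, "LOGR")

    pieces: list[CnaEvent] = []
    for a in ai_segs:
        for l in logr_segs:
            if l.chrom != a.chrom:
                continue
            s, e = max(a.start, l.start), min(a.end, l.end)
            if s > e:
                continue
            if l.value >= logr_gain:
                direction = GAIN
            elif l.value <= logr_loss:
                direction = LOSS
            else:
                direction = CNLOH
            pieces.append(
                CnaEvent(a.chrom, s, e, direction, ai_posterior=a.value, mean_log2=l.value)
            )

    pieces.sort(key=lambda p: (p.chrom, p.start))
    merged: list[CnaEvent] = []
    for p in pieces:
        if (
            merged
            and merged[-1].chrom == p.chrom
            and merged[-1].direction == p.direction
            and p.start <= merged[-1].end + 1
        ):
            prev = merged[-1]
            w1, w2 = prev.length, p.length
            merged[-1] = CnaEvent(
                prev.chrom,
                prev.start,
                max(prev.end, p.end),
                prev.direction,
                ai_posterior=max(prev.ai_posterior, p.ai_posterior),
                mean_log2=(prev.mean_log2 * w1 + p.mean_log2 * w2) / (w1 + w2),
            )
        else:
            merged.append(p)
    return merged


def classify_focal(event: CnaEvent) -> str:
    """``"focal"`` when the event is strictly smaller than 3 Mb, else ``"broad"``."""
    return "focal" if event.length_mb < FOCAL_MB else "broad"


def _arm_covered_fraction(
    events: Iterable[CnaEvent], arms: ArmTable, arm_id: str
) -> float:
    chrom, a_start, a_end = arms.interval(arm_id)
    ivals = [(e.start, e.end) for e in events if e.chrom == chrom]
    return _interval_union_len(ivals, a_start, a_end) / (a_end - a_start + 1)


def aneuploidy_score(events: Sequence[CnaEvent], arms: ArmTable) -> int:
    """Number of arms whose union of CNA bases covers >= 75% of the arm.

    All event directions count; each arm counts at most once.
    """
    for e in events:
        if not arms.contains(e.chrom, e.start, e.end):
            raise ValueError(
                f"event {e.chrom}:{e.start}-{e.end} outside arm table coordinates"
            )
    score = 0
    for arm_id in arms.arm_ids:
        if _arm_covered_fraction(events, arms, arm_id) >= ARM_COVERAGE_FRACTION:
            score += 1
    return score


def arm_amplification_flag(
    events: Sequence[CnaEvent], arms: ArmTable, arm_id: str
) -> bool:
    """True when gain events cover >= 75% of the requested arm (e.g. ``"1q"``)."""
    gains = [e for e in events if e.direction == GAIN]
    return _arm_covered_fraction(gains, arms, arm_id) >= ARM_COVERAGE_FRACTION


def load_gene_table(path=None) -> pd.DataFrame:
    """Gene coordinate table (chrom, start, end, gene); defaults to the toy genome."""
    df = pd.read_csv(path if path is not None else _resource("genes_toy.tsv"), sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    return df


def annotate_genes(
    events: Sequence[CnaEvent],
    genes: pd.DataFrame,
    panel: frozenset[str] | set[str] = CIN_GENES,
) -> pd.DataFrame:
    """Per-gene hit table: any-overlap (>= 1 bp) between gene and event intervals.

    Returns columns gene, chrom, direction, event_start, event_end, focal,
    in_panel — one row per (gene, event) hit.
    """
    rows = []
    for e in events:
        sub = genes[genes["chrom"] == str(e.chrom)]
        for g in sub.itertuples(index=False):
            if _overlap_len(e.start, e.end, g.start, g.end) > 0:
                rows.append(
                    {
                        "gene": g.gene,
                        "chrom": e.chrom,
                        "direction": e.direction,
                        "event_start": e.start,
                        "event_end": e.end,
                        "focal": e.focal,
                        "in_panel": g.gene in panel,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene", "chrom", "direction", "event_start", "event_end", "focal", "in_panel"],
    )


def region_cna_summary(
    events: Sequence[CnaEvent], arms: ArmTable, amplified_arm: str = "1q"
) -> dict:
    """Summary statistics for one region's event list (AS, 1q flag, focal counts)."""
    kinds = [classify_focal(e) for e in events]
    return {
        "aneuploidy_score": aneuploidy_score(events, arms),
        "arm_gain_flag": arm_amplification_flag(events, arms, amplified_arm),
        "n_events": len(events),
        "n_focal": kinds.count("focal"),
        "n_broad": kinds.count("broad"),
    }
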