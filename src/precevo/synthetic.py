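"""Synthetic multi-region cohort simulator with ground truth.

Each simulated patient carries a true clone tree (linear or branched), a
truncal hotspot load (KRAS/GNAS-style), private subclonal SNVs per clone,
arm-scale and focal CNAs (1q gain is preferentially placed on the
high-grade lineage), three emulated callers with distinct sensitivity /
false-positive profiles, AI + log-ratio segment evidence, and expression
replicates drawn from subtype templates.  Everything the pipeline consumes
can be written to disk and read back losslessly.
"""

from __future__ import annotations

import dataclasses
import json
import os
import shutil
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .cna import ArmTable, CnaEvent, Segment, aneuploidy_score, arm_amplification_flag
from .subtype import TemplateSet, default_templates
from .trajectory import (
    BRANCHED,
    Clone,
    CloneTree,
    LINEAR,
    ROOT_ID,
    arm_state_profiles,
    build_cna_tree,
    classify_topology,
)
from .variants import Variant, load_driver_loci

__all__ = [
    "CallerProfile",
    "ExpressionConfig",
    "SimConfig",
    "TrueVariant",
    "RegionSim",
    "PatientSim",
    "Cohort",
    "simulate_clone_tree",
    "simulate_region_calls",
    "simulate_segments",
    "simulate_expression",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

GRADE_SUBTYPE_BASE = {"ND": "exocrine", "AC": "exocrine"}

#: master subtype -> class per classifier (None = flat background)
MASTER_TO_CLASS = {
    "classical": {"moffitt": "classical", "collisson": "classical", "bailey": "progenitor"},
    "basal": {"moffitt": "basal", "collisson": "qm", "bailey": "squamous"},
    "exocrine": {"moffitt": None, "collisson": "exocrine", "bailey": "adex"},
    "none": {"moffitt": None, "collisson": None, "bailey": None},
}


@dataclass(frozen=True)
class CallerProfile:
    """Sensitivity by VAF stratum plus a per-Mb false-positive rate."""

    name: str
    sensitivity: tuple  # ((vaf_upper, sens), ...) ascending in vaf_upper
    fp_rate: float = 0.0  # false calls per Mb

    def sens_at(self, vaf: float) -> float:
        for upper, s in self.sensitivity:
            if vaf <= upper:
                return s
        return self.sensitivity[-1][1]

    def validate(self) -> None:
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be nonnegative")
        for _, s in self.sensitivity:
            if not 0 <= s <= 1:
                raise ValueError("sensitivities must be in [0,1]")


def default_caller_profiles() -> dict[str, CallerProfile]:
    return {
        "M2": CallerProfile(
            "M2", ((0.02, 0.55), (0.05, 0.85), (0.1, 0.95), (1.0, 0.98)), 0.02
        ),
        "SC": CallerProfile(
            "SC", ((0.02, 0.40), (0.05, 0.70), (0.1, 0.90), (1.0, 0.95)), 0.05
        ),
        "MU": CallerProfile(
            "MU", ((0.02, 0.50), (0.05, 0.80), (0.1, 0.93), (1.0, 0.97)), 0.03
        ),
    }


def perfect_caller_profiles() -> dict[str, CallerProfile]:
    return {c: CallerProfile(c, ((1.0, 1.0),), 0.0) for c in ("M2", "SC", "MU")}


@dataclass(frozen=True)
class ExpressionConfig:
    n_genes: int = 160
    noise_sd: float = 0.4
    dropout: float = 0.03
    replicates: tuple = (2, 5)
    background_log2: tuple = (4.0, 6.0)


#: (arm, direction, fraction of arm) menu of candidate CNAs
DEFAULT_CNA_MENU = (
    ("1q", "gain", 0.85),
    ("4p", "loss", 0.80),
    ("2p", "loss", 0.80),
    ("3q", "gain", 0.80),
    ("2q", "gain", 0.78),
    ("1p", "loss", 0.80),
    ("4q", "cnloh", 0.80),
    ("3p", "gain", 0.02),  # focal (< 3 Mb on the toy genome)
)


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 4
    regions_per_patient: tuple = (2, 4)
    mean_depth: int = 400
    topology_mix: tuple = (("linear", 0.5), ("branched", 0.5))
    truncal_hotspots: tuple = (("KRAS", "G12D"), ("GNAS", "R201C"))
    n_subclonal_snvs: tuple = (18, 36)
    cna_menu: tuple = DEFAULT_CNA_MENU
    caller_profiles: tuple = tuple(sorted(default_caller_profiles().items()))
    expression: ExpressionConfig = ExpressionConfig()
    purity_range: tuple = (0.35, 0.9)
    captured_mb: float = 40.0
    mu_missing_prob: float = 0.1
    seg_noise_sd: float = 0.04
    logr_gain_mean: float = 0.4
    logr_loss_mean: float = -0.45
    vaf_noise: bool = True
    depth_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("depth must be positive")
        if abs(sum(w for _, w in self.topology_mix) - 1.0) > 1e-9:
            raise ValueError("topology_mix must sum to 1")
        for _, w in self.topology_mix:
            if not 0 <= w <= 1:
                raise ValueError("topology_mix weights must be in [0,1]")
        if not 0 <= self.mu_missing_prob <= 1:
            raise ValueError("mu_missing_prob must be in [0,1]")
        if not 0 <= self.expression.dropout <= 1:
            raise ValueError("dropout must be in [0,1]")
        for _, prof in self.caller_profiles:
            prof.validate()

    @property
    def profiles(self) -> dict[str, CallerProfile]:
        return dict(self.caller_profiles)

    @classmethod
    def noiseless(cls, **kw) -> "SimConfig":
        """Perfect sensitivity, no false positives, no noise anywhere."""
        defaults = dict(
            caller_profiles=tuple(sorted(perfect_caller_profiles().items())),
            expression=ExpressionConfig(noise_sd=0.0, dropout=0.0),
            mu_missing_prob=0.0,
            seg_noise_sd=0.0,
            vaf_noise=False,
            depth_noise=False,
        )
        defaults.update(kw)
        return cls(**defaults)


@dataclass(frozen=True)
class TrueVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str = "SNV"
    gene: str | None = None
    clone: str = ""
    hotspot: bool = False

    @property
    def key(self):
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class RegionSim:
    region: str
    patient: str
    grade: str
    purity: float
    n_replicates: int
    subtype: str  # master label
    true_variants: list = field(default_factory=list)  # TrueVariant present here
    true_events: list = field(default_factory=list)  # CnaEvent list
    caller_calls: dict = field(default_factory=dict)  # caller -> [Variant]
    ai_segments: list = field(default_factory=list)
    logr_segments: list = field(default_factory=list)

    def truth_summary(self, arms: ArmTable, captured_mb: float) -> dict:
        return {
            "n_variants": len(self.true_variants),
            "burden": len(self.true_variants) / captured_mb,
            "aneuploidy_score": aneuploidy_score(self.true_events, arms),
            "flag_1q": arm_amplification_flag(self.true_events, arms, "1q"),
        }


@dataclass
class PatientSim:
    patient: str
    tree: CloneTree
    topology: str
    cna_topology: str
    regions: list
    mu_available: bool = True

    @property
    def grades(self) -> dict[str, str]:
        return {r.region: r.grade for r in self.regions}

    def region(self, region_id: str) -> RegionSim:
        for r in self.regions:
            if r.region == region_id:
                return r
        raise KeyError(f"unknown region {region_id!r}")


@dataclass
class Cohort:
    config: SimConfig
    arms: ArmTable
    patients: list
    expression: pd.DataFrame  # genes x replicates (integer counts)
    replicate_regions: dict  # replicate column -> region id
    templates: dict  # name -> TemplateSet


# ---------------------------------------------------------------------------
# clone trees
# ---------------------------------------------------------------------------

def _descending_ccfs(rng, n: int, leaf_ccf: float, min_gap: float = 0.05) -> list[float]:
    """n CCF values 1.0 = c_1 > ... > c_n = leaf_ccf with gaps >= min_gap."""
    if n == 1:
        return [1.0]
    slack = 1.0 - leaf_ccf - min_gap * (n - 1)
    extra = rng.dirichlet(np.ones(n - 1)) * max(0.0, slack)
    ccfs = [1.0]
    for i in range(n - 1):
        ccfs.append(ccfs[-1] - min_gap - extra[i])
    ccfs[-1] = leaf_ccf
    return [round(float(c), 4) for c in ccfs]


def _chain_fractions(ccfs: Sequence[float], ids: Sequence[str]) -> dict[str, float]:
    out = {}
    for i, cid in enumerate(ids):
        nxt = ccfs[i + 1] if i + 1 < len(ccfs) else 0.0
        out[cid] = round(ccfs[i] - nxt, 4)
    return out


def simulate_clone_tree(
    n_clones: int,
    topology: str,
    seed: int,
    mut_ids: Mapping[str, frozenset] | None = None,
) -> CloneTree:
    """A ground-truth clone tree over regions LG and HG of the given topology.

    Linear: a single chain whose deepest clone dominates the HG region and is
    absent from the LG; every shallower clone is LG-present.  Branched: a
    truncal clone with separate LG- and HG-dominant chains.  Clone mutation
    sets default to abstract placeholders unless ``mut_ids`` supplies them.
    """
    if n_clones < 2:
        raise ValueError("degenerate tree: need at least 2 clones")
    rng = np.random.default_rng(seed)
    ids = [f"C{i + 1}" for i in range(n_clones)]

    if topology == LINEAR:
        parents = {ids[0]: ROOT_ID}
        for a, b in zip(ids, ids[1:]):
            parents[b] = a
        hg_ccfs = _descending_ccfs(rng, n_clones, round(float(rng.uniform(0.55, 0.75)), 4))
        lg_chain = ids[:-1]
        if len(lg_chain) == 0:
            raise ValueError("degenerate tree")
        lg_ccfs = _descending_ccfs(
            rng, len(lg_chain), round(float(rng.uniform(0.55, 0.7)), 4)
        )
        fractions = {
            "HG": _chain_fractions(hg_ccfs, ids),
            "LG": {**_chain_fractions(lg_ccfs, lg_chain), ids[-1]: 0.0},
        }
    elif topology == BRANCHED:
        if n_clones < 3:
            raise ValueError("branched topology needs at least 3 clones")
        trunk = ids[0]
        rest = ids[1:]
        n_lg = max(1, len(rest) // 2)
        lg_branch, hg_branch = rest[:n_lg], rest[n_lg:]
        parents = {trunk: ROOT_ID}
        for branch in (lg_branch, hg_branch):
            prev = trunk
            for cid in branch:
                parents[cid] = prev
                prev = cid

        def branch_fractions(own: list[str], other: list[str], rng) -> dict[str, float]:
            head_ccf = round(float(rng.uniform(0.75, 0.9)), 4)
            leaf_ccf = round(float(rng.uniform(0.55, min(0.7, head_ccf))), 4)
            ccfs = [round(c * head_ccf, 4) for c in _descending_ccfs(rng, len(own), leaf_ccf / head_ccf)]
            fr = {trunk: round(1.0 - ccfs[0], 4)}
            fr.update(_chain_fractions(ccfs, own))
            fr.update({cid: 0.0 for cid in other})
            return fr

        fractions = {
            "LG": branch_fractions(lg_branch, hg_branch, rng),
            "HG": branch_fractions(hg_branch, lg_branch, rng),
        }
    else:
        raise ValueError(f"unknown topology {topology!r}")

    muts: dict[str, frozenset] = {ROOT_ID: frozenset()}
    clones = []
    for cid in ids:
        own = (
            frozenset(mut_ids.get(cid, frozenset()))
            if mut_ids is not None
            else frozenset({("sim", seed, cid, k) for k in range(3)})
        )
        muts[cid] = muts[parents[cid]] | own
        clones.append(Clone(cid, parents[cid], muts=muts[cid]))
    return CloneTree(clones, fractions, topology=topology)


def _extend_fractions_for_region(tree: CloneTree, grade: str, rng) -> dict[str, float]:
    """Clone fractions for an extra region of the given grade."""
    if grade in ("ND", "AC"):
        return {cid: 0.0 for cid in tree.clones if cid != ROOT_ID}
    # PDAC: push the HG-dominant lineage further toward fixation
    hg_fr = dict(tree.fractions["HG"])
    dom = max(hg_fr, key=lambda c: (hg_fr[c], c))
    boost = round(float(rng.uniform(0.1, 0.2)), 4)
    out = {}
    for cid, f in hg_fr.items():
        if cid == dom:
            out[cid] = round(min(1.0, f + boost), 4)
        else:
            out[cid] = round(max(0.0, f * (1 - boost)), 4)
    total = sum(out.values())
    if total > 0.9999:
        out = {c: round(f * 0.9995 / total, 4) for c, f in out.items()}
    return out


# ---------------------------------------------------------------------------
# per-region evidence
# ---------------------------------------------------------------------------

def _region_expected_vaf(patient: PatientSim, region: RegionSim, v: TrueVariant) -> float:
    ccf = patient.tree.ccf(region.region, v.clone)
    return region.purity * ccf / 2.0


def simulate_region_calls(
    patient: PatientSim,
    region_id: str,
    profiles: Mapping[str, CallerProfile],
    seed: int,
    mean_depth: int = 400,
    arms: ArmTable | None = None,
    vaf_noise: bool = True,
    depth_noise: bool = True,
    capture_mb: float = 40.0,
) -> dict[str, list[Variant]]:
    """Per-caller call sets for one region.

    Every true variant present in the region is observed once (shared depth
    and VAF across callers) and enters each caller's set independently with
    the caller's VAF-stratum sensitivity; false positives are placed
    uniformly over the genome at the caller's per-Mb rate.
    """
    region = patient.region(region_id)
    arms = arms or ArmTable.toy()
    rng = np.random.default_rng(seed)
    out: dict[str, list[Variant]] = {name: [] for name in profiles}

    observed: list[tuple[TrueVariant, Variant]] = []
    for tv in region.true_variants:
        evaf = _region_expected_vaf(patient, region, tv)
        if evaf <= 0:
            continue
        depth = int(rng.poisson(mean_depth)) if depth_noise else int(mean_depth)
        depth = max(depth, 50)
        alt = int(rng.binomial(depth, min(evaf, 1.0))) if vaf_noise else int(round(depth * evaf))
        if alt == 0:
            continue
        quality = round(float(rng.uniform(2.0, 80.0)), 2)
        base = Variant(
            chrom=tv.chrom,
            pos=tv.pos,
            ref=tv.ref,
            alt=tv.alt,
            vtype=tv.vtype,
            tumor_depth=depth,
            tumor_alt=alt,
            normal_depth=mean_depth,
            normal_alt=0,
            quality=quality,
            pop_af=None,
            predictor_verdicts=(True, True, True, True, False, False, False)
            if tv.hotspot
            else (True, True, False, False, False, False, False),
            clinvar="pathogenic" if tv.hotspot else "absent",
            func_class="exonic",
            gene=tv.gene,
        )
        observed.append((tv, base))

    for name in sorted(profiles):
        prof = profiles[name]
        for tv, base in observed:
            evaf = _region_expected_vaf(patient, region, tv)
            if rng.random() < prof.sens_at(evaf):
                out[name].append(
                    dataclasses.replace(base, callers=frozenset({name}))
                )
        # false positives: rate is per Mb of captured space, sites uniform
        n_fp = int(rng.poisson(prof.fp_rate * capture_mb))
        for _ in range(n_fp):
            chrom, pos = _random_site(rng, arms)
            ref, alt_b = _random_alleles(rng)
            depth = int(rng.poisson(mean_depth)) if depth_noise else int(mean_depth)
            depth = max(depth, 50)
            alt_n = max(1, int(round(depth * rng.uniform(0.01, 0.08))))
            has_af = rng.random() < 0.3
            out[name].append(
                Variant(
                    chrom=chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt_b,
                    vtype="SNV",
                    tumor_depth=depth,
                    tumor_alt=alt_n,
                    normal_depth=mean_depth,
                    normal_alt=0,
                    callers=frozenset({name}),
                    quality=round(float(rng.uniform(1.0, 10.0)), 2),
                    pop_af=round(float(rng.uniform(0.011, 0.2)), 6) if has_af else None,
                    predictor_verdicts=(False,) * 7,
                    clinvar="absent",
                    func_class="other" if rng.random() < 0.5 else "exonic",
                    gene=None,
                )
            )
    return out


def _random_site(rng, arms: ArmTable) -> tuple[str, int]:
    rows = list(arms)
    lengths = np.array([r.end - r.start + 1 for r in rows], dtype=float)
    row = rows[int(rng.choice(len(rows), p=lengths / lengths.sum()))]
    return str(row.chrom), int(rng.integers(row.start, row.end + 1))


def _random_alleles(rng) -> tuple[str, str]:
    bases = ["A", "C", "G", "T"]
    ref = bases[int(rng.integers(4))]
    alt = bases[int(rng.integers(4))]
    while alt == ref:
        alt = bases[int(rng.integers(4))]
    return ref, alt


def simulate_segments(
    patient: PatientSim,
    region_id: str,
    seed: int,
    arms: ArmTable | None = None,
    noise_sd: float = 0.04,
    gain_mean: float = 0.4,
    loss_mean: float = -0.45,
) -> tuple[list[Segment], list[Segment]]:
    """AI and log-ratio segment tables implied by the region's true events."""
    region = patient.region(region_id)
    arms = arms or ArmTable.toy()
    rng = np.random.default_rng(seed)

    ai = []
    event_means = {}
    for e in sorted(region.true_events, key=lambda x: (x.chrom, x.start)):
        ai.append(
            Segment(e.chrom, e.start, e.end, "AI", round(float(rng.uniform(0.95, 0.999)), 4))
        )
        mean = {"gain": gain_mean, "loss": loss_mean, "cnloh": 0.0}[e.direction]
        event_means[(e.chrom, e.start, e.end)] = round(
            float(mean + rng.normal(0, noise_sd)), 4
        )

    logr = []
    for chrom in sorted({str(r.chrom) for r in arms}):
        bounds = [
            (r.start, r.end) for r in arms.rows_for_chrom(chrom)
        ]
        chrom_start = min(s for s, _ in bounds)
        chrom_end = max(e for _, e in bounds)
        events = sorted(
            [e for e in region.true_events if e.chrom == chrom], key=lambda x: x.start
        )
        cursor = chrom_start
        for e in events:
            if e.start > cursor:
                logr.append(
                    Segment(
                        chrom, cursor, e.start - 1, "LOGR",
                        round(float(rng.normal(0, noise_sd)), 4),
                    )
                )
            logr.append(
                Segment(chrom, e.start, e.end, "LOGR", event_means[(e.chrom, e.start, e.end)])
            )
            cursor = e.end + 1
        if cursor <= chrom_end:
            logr.append(
                Segment(
                    chrom, cursor, chrom_end, "LOGR",
                    round(float(rng.normal(0, noise_sd)), 4),
                )
            )
    return ai, logr


def simulate_expression(
    region_subtype: str,
    templates: Mapping[str, TemplateSet],
    cfg: SimConfig,
    seed: int,
    n_replicates: int = 1,
    region_id: str = "R",
    background: pd.Series | None = None,
) -> pd.DataFrame:
    """Expression count replicates for one region (genes x replicates).

    Template genes of each classifier follow the centroid of the class the
    master subtype maps to; unmapped classifiers and background genes follow
    a flat base profile.  Counts are 2^(log2 level + noise) − 1, rounded,
    with dropout zeros.
    """
    if region_subtype not in MASTER_TO_CLASS:
        raise ValueError(f"unknown template class {region_subtype!r}")
    rng = np.random.default_rng(seed)
    expr = cfg.expression
    mapping = MASTER_TO_CLASS[region_subtype]

    levels = {}
    for name, tset in sorted(templates.items()):
        cls = mapping.get(name)
        for g in tset.genes:
            if cls is not None and cls in tset.classes:
                levels[g] = float(tset.weights.loc[g, cls])
            else:
                levels[g] = 3.0
    n_background = max(0, expr.n_genes - len(levels))
    if background is None:
        bg_rng = np.random.default_rng(0)  # background levels fixed across cohorts
        background = pd.Series(
            np.round(bg_rng.uniform(*expr.background_log2, size=n_background), 2),
            index=[f"BG{i + 1:03d}" for i in range(n_background)],
        )
    for g, w in background.items():
        levels[g] = float(w)

    genes = sorted(levels)
    base = np.array([levels[g] for g in genes])
    cols = {}
    for j in range(n_replicates):
        noise = rng.normal(0, expr.noise_sd, size=len(genes)) if expr.noise_sd > 0 else 0.0
        counts = np.round(np.power(2.0, base + noise) - 1.0).astype(int)
        counts = np.maximum(counts, 0)
        if expr.dropout > 0:
            counts[rng.random(len(genes)) < expr.dropout] = 0
        cols[f"{region_id}.rep{j + 1}"] = counts
    return pd.DataFrame(cols, index=genes)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _choose_topology(rng, mix) -> str:
    names = [n for n, _ in mix]
    weights = np.array([w for _, w in mix])
    return names[int(rng.choice(len(names), p=weights / weights.sum()))]


def _event_from_menu(entry, arms: ArmTable) -> CnaEvent:
    arm_id, direction, frac = entry
    chrom, start, end = arms.interval(arm_id)
    length = max(1, int(round(frac * (end - start + 1))))
    return CnaEvent(chrom, start, start + length - 1, direction)


def _sample_positions(rng, arms: ArmTable, n: int, forbidden, blocked_intervals):
    out = []
    while len(out) < n:
        chrom, pos = _random_site(rng, arms)
        if (chrom, pos) in forbidden:
            continue
        if any(c == chrom and s <= pos <= e for c, s, e in blocked_intervals):
            continue
        forbidden.add((chrom, pos))
        out.append((chrom, pos))
    return out


def simulate_cohort(cfg: SimConfig, arms: ArmTable | None = None) -> Cohort:
    """Simulate a full cohort (trees, variants, CNAs, calls, segments, expression)."""
    arms = arms or ArmTable.toy()
    templates = default_templates()
    driver_sites = load_driver_loci()
    hotspot_by_gene = {g: site for site, g in driver_sites.items()}

    ss = np.random.SeedSequence(cfg.seed)
    patient_seeds = ss.spawn(cfg.n_patients)
    patients = []
    expr_frames = []
    replicate_regions: dict[str, str] = {}

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:02d}"
        pseed = patient_seeds[i]
        rng = np.random.default_rng(pseed)
        topology = _choose_topology(rng, cfg.topology_mix)
        n_clones = int(rng.integers(3, 5)) if topology == BRANCHED else int(rng.integers(2, 5))

        # region roster: always one LG and one HG, extras from ND/AC/PDAC
        n_regions = int(rng.integers(cfg.regions_per_patient[0], cfg.regions_per_patient[1] + 1))
        grades = ["LG", "HG"]
        extra_pool = ["ND", "AC", "PDAC"]
        for j in range(max(0, n_regions - 2)):
            pick = extra_pool[int(rng.integers(len(extra_pool)))]
            if pick == "PDAC" and "PDAC" in grades:
                pick = "ND"
            grades.append(pick)

        # CNA assignment: distinct arms per patient; the HG lineage always
        # carries at least one broad event (1q gain preferred)
        menu = list(cfg.cna_menu)
        broad = [m for m in menu if m[2] * arms.length(m[0]) / 1e6 >= 5.0]
        focal = [m for m in menu if m not in broad]
        rng.shuffle(broad)
        one_q = next((m for m in broad if m[0] == "1q" and m[1] == "gain"), None)
        if one_q and rng.random() < 0.8:
            broad.remove(one_q)
            broad.insert(0, one_q)
        trunk_events = []
        if rng.random() < 0.4 and len(broad) > 2:
            trunk_events = [broad.pop()]
        hg_events = [broad.pop(0)]
        if broad and rng.random() < 0.4:
            hg_events.append(broad.pop(0))
        lg_events = [broad.pop(0)] if broad and rng.random() < 0.6 else []
        if focal and rng.random() < 0.5:
            hg_events.append(focal[int(rng.integers(len(focal)))])

        # tree skeleton first (to know clones), mutations second
        skeleton = simulate_clone_tree(n_clones, topology, int(rng.integers(2**31)))
        clone_ids = [c for c in skeleton.clones if c != ROOT_ID]

        # per-clone mutation sets
        blocked = [
            (ev.chrom, ev.start, ev.end)
            for ev in (
                _event_from_menu(m, arms) for m in trunk_events + hg_events + lg_events
            )
        ]
        forbidden = set(driver_sites)
        n_sub = int(rng.integers(cfg.n_subclonal_snvs[0], cfg.n_subclonal_snvs[1] + 1))
        per_clone = max(4, n_sub // max(1, len(clone_ids)))

        true_variants: list[TrueVariant] = []
        mut_ids: dict[str, set] = {c: set() for c in clone_ids}
        trunk_id = skeleton.ancestors(clone_ids[0])[0]
        for gene, label in cfg.truncal_hotspots:
            chrom, pos = hotspot_by_gene[gene]
            ref, alt = ("G", "A")
            tv = TrueVariant(chrom, pos, ref, alt, "SNV", gene, trunk_id, hotspot=True)
            true_variants.append(tv)
            mut_ids[trunk_id].add(tv.key)
        n_indels = 2
        for cid in clone_ids:
            n_here = per_clone + (n_indels if cid == trunk_id else 0)
            for k, (chrom, pos) in enumerate(
                _sample_positions(rng, arms, n_here, forbidden, blocked)
            ):
                is_indel = cid == trunk_id and k < n_indels
                if is_indel:
                    ref, alt = "AT", "A"
                else:
                    ref, alt = _random_alleles(rng)
                tv = TrueVariant(
                    chrom, pos, ref, alt, "indel" if is_indel else "SNV", None, cid
                )
                true_variants.append(tv)
                mut_ids[cid].add(tv.key)

        tree = CloneTree(
            [
                Clone(cid, skeleton.clones[cid].parent,
                      muts=_accumulate_muts(skeleton, mut_ids, cid),
                      events=_clone_events(skeleton, cid, trunk_id, topology,
                                           trunk_events, hg_events, lg_events))
                for cid in clone_ids
            ],
            skeleton.fractions,
            topology=topology,
        )

        # region construction
        regions = []
        used = {"LG": 0, "HG": 0, "ND": 0, "AC": 0, "PDAC": 0}
        region_fracs = {}
        for grade in grades:
            used[grade] += 1
            rid = f"{pid}_{grade}" + (str(used[grade]) if used[grade] > 1 else "")
            if grade in ("LG", "HG"):
                fr = tree.fractions[grade]
            else:
                fr = _extend_fractions_for_region(tree, grade, rng)
            region_fracs[rid] = fr
            purity = (
                0.0
                if grade in ("ND", "AC")
                else round(float(rng.uniform(*cfg.purity_range)), 2)
            )
            subtype = _region_subtype(rng, grade, regions)
            n_rep = int(rng.integers(cfg.expression.replicates[0], cfg.expression.replicates[1] + 1))
            regions.append(
                RegionSim(rid, pid, grade, purity, n_rep, subtype)
            )
        # rebuild the tree over actual region ids
        tree = CloneTree(
            [tree.clones[c] for c in clone_ids], region_fracs, topology=topology
        )

        patient = PatientSim(pid, tree, topology, "", regions)
        patient.mu_available = bool(rng.random() >= cfg.mu_missing_prob)

        # per-region truth: variants present, events detectable
        events_by_clone = {cid: tree.clones[cid].events for cid in clone_ids}
        for region in regions:
            region.true_variants = [
                tv
                for tv in true_variants
                if tree.ccf(region.region, tv.clone) > 0 and region.purity > 0
            ]
            ev = []
            for cid in clone_ids:
                if tree.ccf(region.region, cid) >= 0.3 and region.purity > 0:
                    for key in sorted(events_by_clone[cid]):
                        ev.append(_event_from_menu(_menu_entry(key), arms))
            region.true_events = sorted(ev, key=lambda e: (e.chrom, e.start))

        # evidence layers
        region_seeds = pseed.spawn(len(regions))
        for region, rseed in zip(regions, region_seeds):
            child = rseed.spawn(3)
            region.caller_calls = simulate_region_calls(
                patient,
                region.region,
                cfg.profiles,
                seed=int(child[0].generate_state(1)[0]),
                mean_depth=cfg.mean_depth,
                arms=arms,
                vaf_noise=cfg.vaf_noise,
                depth_noise=cfg.depth_noise,
                capture_mb=cfg.captured_mb,
            )
            if not patient.mu_available:
                region.caller_calls["MU"] = []
            region.ai_segments, region.logr_segments = simulate_segments(
                patient,
                region.region,
                seed=int(child[1].generate_state(1)[0]),
                arms=arms,
                noise_sd=cfg.seg_noise_sd,
                gain_mean=cfg.logr_gain_mean,
                loss_mean=cfg.logr_loss_mean,
            )
            frame = simulate_expression(
                region.subtype,
                templates,
                cfg,
                seed=int(child[2].generate_state(1)[0]),
                n_replicates=region.n_replicates,
                region_id=region.region,
            )
            expr_frames.append(frame)
            for col in frame.columns:
                replicate_regions[col] = region.region

        # CNA-route truth label, derived by running the parsimony classifier
        # on the true region events
        profiles_true = arm_state_profiles(
            {r.region: r.true_events for r in regions}, arms
        )
        patient.cna_topology = build_cna_tree(profiles_true, patient.grades).classification
        patients.append(patient)

    expression = pd.concat(expr_frames, axis=1) if expr_frames else pd.DataFrame()
    return Cohort(cfg, arms, patients, expression, replicate_regions, templates)


def _accumulate_muts(skeleton: CloneTree, mut_ids, cid: str) -> frozenset:
    out: set = set()
    for anc in skeleton.ancestors(cid):
        out |= mut_ids.get(anc, set())
    return frozenset(out)


def _menu_entry(key: str):
    arm_id, direction, frac = key.split(":")
    return (arm_id, direction, float(frac))


def _event_key(entry) -> str:
    return f"{entry[0]}:{entry[1]}:{entry[2]}"


def _clone_events(
    skeleton: CloneTree, cid: str, trunk_id: str, topology: str,
    trunk_events, hg_events, lg_events,
) -> frozenset:
    """Attach CNA events: trunk events on the trunk, lineage events on the
    dominant LG / HG clones."""
    out = set()
    if cid == trunk_id:
        out |= {_event_key(m) for m in trunk_events}
    lg_dom = skeleton.dominant("LG")
    hg_dom = skeleton.dominant("HG")
    if cid == hg_dom:
        out |= {_event_key(m) for m in hg_events}
    if cid == lg_dom and cid != hg_dom:
        out |= {_event_key(m) for m in lg_events}
    return frozenset(out)


def _region_subtype(rng, grade: str, prior_regions: list) -> str:
    if grade in GRADE_SUBTYPE_BASE:
        return GRADE_SUBTYPE_BASE[grade]
    if rng.random() < 0.05:
        return "none"
    lg = next((r.subtype for r in prior_regions if r.grade == "LG"), None)
    if grade == "LG" or lg is None or lg in ("exocrine", "none"):
        return "classical" if rng.random() < 0.65 else "basal"
    # HG / PDAC: persist the LG subtype 80% of the time
    if rng.random() < 0.8:
        return lg
    return "basal" if lg == "classical" else "classical"


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def _tree_to_json(tree: CloneTree) -> dict:
    return tree.to_dict()


def _tree_from_json(d: dict) -> CloneTree:
    clones = []
    for cid, spec in d["clones"].items():
        if cid == ROOT_ID:
            continue
        clones.append(
            Clone(
                cid,
                spec["parent"],
                muts=frozenset(tuple(m) for m in spec["muts"]),
                events=frozenset(spec["events"]),
            )
        )
    return CloneTree(
        clones, d["fractions"], topology=d.get("topology"), unresolved=d.get("unresolved", False)
    )


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write the cohort file tree; returns the manifest dictionary."""
    out = os.fspath(out_dir)
    os.makedirs(out, exist_ok=True)
    arms_path = os.path.join(out, "arms.tsv")
    cohort.arms.df.to_csv(arms_path, sep="\t", index=False)
    shutil.copy(
        _importlib_resources.files("precevo.resources") / "genes_toy.tsv",
        os.path.join(out, "genes.tsv"),
    )
    tdir = os.path.join(out, "templates")
    os.makedirs(tdir, exist_ok=True)
    for name, tset in cohort.templates.items():
        tset.weights.reset_index().melt(
            id_vars="gene", var_name="class", value_name="weight"
        ).sort_values(["gene", "class"]).to_csv(
            os.path.join(tdir, f"{name}.tsv"), sep="\t", index=False,
            float_format="%.2f",
        )

    contigs = {
        chrom: int(max(r.end for r in cohort.arms.rows_for_chrom(chrom)))
        for chrom in sorted({str(r.chrom) for r in cohort.arms})
    }

    manifest: dict = {"config": _config_to_json(cohort.config), "patients": []}
    truth: dict = {"patients": {}}
    for patient in cohort.patients:
        pdirs = []
        for region in patient.regions:
            rdir = os.path.join(out, "patients", patient.patient, region.region)
            os.makedirs(rdir, exist_ok=True)
            files = {}
            for caller, calls in sorted(region.caller_calls.items()):
                if caller == "MU" and not patient.mu_available:
                    continue
                fname = f"{caller}.vcf"
                pio.write_vcf(calls, os.path.join(rdir, fname), contigs)
                files[caller] = fname
            pio.write_ai_table(region.ai_segments, os.path.join(rdir, "ai.tsv"))
            pio.write_seg_table(
                region.logr_segments, os.path.join(rdir, "logr.seg"), region.region
            )
            pdirs.append(
                {
                    "id": region.region,
                    "grade": region.grade,
                    "purity": region.purity,
                    "n_replicates": region.n_replicates,
                    "vcfs": files,
                }
            )
        manifest["patients"].append(
            {"id": patient.patient, "mu_available": patient.mu_available, "regions": pdirs}
        )
        truth["patients"][patient.patient] = {
            "tree": _tree_to_json(patient.tree),
            "topology": patient.topology,
            "cna_topology": patient.cna_topology,
            "regions": {
                r.region: {
                    "grade": r.grade,
                    "purity": r.purity,
                    "subtype": r.subtype,
                    "n_replicates": r.n_replicates,
                    "variants": [
                        dataclasses.asdict(tv) for tv in r.true_variants
                    ],
                    "events": [
                        {
                            "chrom": e.chrom,
                            "start": e.start,
                            "end": e.end,
                            "direction": e.direction,
                        }
                        for e in r.true_events
                    ],
                    **r.truth_summary(cohort.arms, cohort.config.captured_mb),
                }
                for r in patient.regions
            },
        }

    edir = os.path.join(out, "expression")
    os.makedirs(edir, exist_ok=True)
    cohort.expression.rename_axis("gene").to_csv(
        os.path.join(edir, "counts.tsv"), sep="\t"
    )
    manifest["replicate_regions"] = cohort.replicate_regions
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(os.path.join(out, "truth.json"), "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return manifest


def _config_to_json(cfg: SimConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["caller_profiles"] = [
        [name, dataclasses.asdict(prof)] for name, prof in cfg.caller_profiles
    ]
    return d


def _config_from_json(d: dict) -> SimConfig:
    d = dict(d)
    d["caller_profiles"] = tuple(
        (
            name,
            CallerProfile(
                spec["name"],
                tuple(tuple(x) for x in spec["sensitivity"]),
                spec["fp_rate"],
            ),
        )
        for name, spec in d["caller_profiles"]
    )
    d["expression"] = ExpressionConfig(
        **{**d["expression"], "replicates": tuple(d["expression"]["replicates"]),
           "background_log2": tuple(d["expression"]["background_log2"])}
    )
    for key in (
        "regions_per_patient", "n_subclonal_snvs", "purity_range",
    ):
        d[key] = tuple(d[key])
    d["topology_mix"] = tuple((n, w) for n, w in d["topology_mix"])
    d["truncal_hotspots"] = tuple((g, s) for g, s in d["truncal_hotspots"])
    d["cna_menu"] = tuple((a, dir_, f) for a, dir_, f in d["cna_menu"])
    return SimConfig(**d)


def read_cohort(in_dir) -> Cohort:
    """Rebuild a :class:`Cohort` from a directory written by :func:`write_cohort`."""
    base = os.fspath(in_dir)
    with open(os.path.join(base, "manifest.json")) as fh:
        manifest = json.load(fh)
    with open(os.path.join(base, "truth.json")) as fh:
        truth = json.load(fh)
    cfg = _config_from_json(manifest["config"])
    arms = ArmTable.from_tsv(os.path.join(base, "arms.tsv"))
    tdir = os.path.join(base, "templates")
    templates = {
        os.path.splitext(f)[0]: TemplateSet.from_tsv(os.path.join(tdir, f))
        for f in sorted(os.listdir(tdir))
    }

    patients = []
    for pspec in manifest["patients"]:
        pid = pspec["id"]
        tspec = truth["patients"][pid]
        tree = _tree_from_json(tspec["tree"])
        regions = []
        for rspec in pspec["regions"]:
            rid = rspec["id"]
            rtruth = tspec["regions"][rid]
            rdir = os.path.join(base, "patients", pid, rid)
            calls = {
                caller: pio.read_vcf(os.path.join(rdir, fname), caller)
                for caller, fname in sorted(rspec["vcfs"].items())
            }
            if not pspec["mu_available"]:
                calls["MU"] = []
            region = RegionSim(
                rid,
                pid,
                rspec["grade"],
                float(rspec["purity"]),
                int(rspec["n_replicates"]),
                rtruth["subtype"],
                true_variants=[
                    TrueVariant(**{**tv, "gene": tv["gene"]}) for tv in rtruth["variants"]
                ],
                true_events=[
                    CnaEvent(e["chrom"], e["start"], e["end"], e["direction"])
                    for e in rtruth["events"]
                ],
                caller_calls=calls,
                ai_segments=pio.read_ai_table(os.path.join(rdir, "ai.tsv")),
                logr_segments=pio.read_seg_table(os.path.join(rdir, "logr.seg")),
            )
            regions.append(region)
        patient = PatientSim(
            pid, tree, tspec["topology"], tspec["cna_topology"], regions,
            mu_available=bool(pspec["mu_available"]),
        )
        patients.append(patient)

    expression = pd.read_csv(
        os.path.join(base, "expression", "counts.tsv"), sep="\t", index_col="gene"
    )
    return Cohort(
        cfg, arms, patients, expression, dict(manifest["replicate_regions"]), templates
    )
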