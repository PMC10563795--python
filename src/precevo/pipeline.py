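"""End-to-end cohort driver: variants → CNA → trees → subtype → statistics.

Consumes a cohort directory written by :func:`precevo.synthetic.write_cohort`
(or any directory matching that layout) and emits a nested report with
per-region summaries, per-patient trajectory labels, and cohort-level tables
and tests.  Deterministic given the input directory and seed.
"""

from __future__ import annotations

import dataclasses
import json
import os
from typing import Mapping

import pandas as pd

from . import io as pio
from .cna import (
    ArmTable,
    CnaEvent,
    overlay_cna,
    region_cna_summary,
)
from .stats import ContingencyTable2x2, compare_grades, exact_2x2
from .subtype import (
    NONCLASSIFIABLE,
    TemplateSet,
    aggregate_replicates,
    class_switches,
    classify_replicates,
    normalize_counts,
)
from .trajectory import (
    arm_state_profiles,
    build_cna_tree,
    build_snv_tree,
    classify_topology,
    cluster_variants,
    compare_trajectories,
    detect_minor_expansion,
)
from .variants import (
    RescuePanel,
    Variant,
    consensus_calls,
    filter_indels,
    load_driver_loci,
    mutation_burden,
    population_filter,
    rescue_targeted,
    single_caller_calls,
)

__all__ = ["PipelineConfig", "run_pipeline", "score_recovery"]


@dataclasses.dataclass
class PipelineConfig:
    captured_mb: float = 40.0
    max_pop_af: float = 0.01
    logr_gain: float = 0.2
    logr_loss: float = -0.2
    presence_threshold: float = 0.01
    cluster_distance: float = 0.3
    min_cluster_variants: int = 3
    containment_tol: float = 0.15
    min_cna_tree_mb: float = 5.0
    n_perm: int = 1000
    fdr_threshold: float = 0.05
    rescue: bool = True
    blocklist: frozenset = frozenset()  # optional (chrom, pos) site blocklist
    seed: int = 0


def _region_variant_calls(
    rdir: str, vcfs: Mapping[str, str]
) -> dict[str, list[Variant]]:
    return {
        caller: pio.read_vcf(os.path.join(rdir, fname), caller)
        for caller, fname in sorted(vcfs.items())
    }


def harmonize_region(
    per_caller: Mapping[str, list[Variant]],
    cfg: PipelineConfig,
    panel: RescuePanel | None = None,
) -> dict:
    """Consensus + filters + rescue for one region; returns variants and burden."""
    available = [c for c in ("M2", "SC", "MU") if c in per_caller]
    consensus = consensus_calls(per_caller, available)
    consensus = population_filter(consensus, cfg.max_pop_af)
    snvs = [v for v in consensus if v.vtype == "SNV"]
    indels = filter_indels([v for v in consensus if v.vtype == "indel"])
    kept = snvs + indels
    if cfg.blocklist:
        kept = [v for v in kept if v.site not in cfg.blocklist]

    rescued: list[Variant] = []
    if cfg.rescue and panel is not None:
        singles = single_caller_calls(per_caller, available)
        singles = population_filter(singles, cfg.max_pop_af)
        rescued = rescue_targeted(singles, panel, consensus=kept)
    return {
        "variants": kept,
        "rescued": rescued,
        "burden": mutation_burden(kept + rescued, cfg.captured_mb),
    }


def _patient_vaf_matrix(
    region_variants: Mapping[str, list[Variant]],
    cna_events: Mapping[str, list[CnaEvent]],
) -> pd.DataFrame:
    """Regions x variants VAF matrix; sites inside called CNAs are excluded."""

    def in_cna(v: Variant, region: str) -> bool:
        return any(
            e.chrom == v.chrom and e.start <= v.pos <= e.end
            for e in cna_events.get(region, [])
        )

    keys = sorted(
        {
            v.key
            for region, vs in region_variants.items()
            for v in vs
            if not any(in_cna(v, r) for r in region_variants)
        }
    )
    data = {}
    for region, vs in region_variants.items():
        by_key = {v.key: v.vaf for v in vs}
        data[region] = [by_key.get(k, 0.0) for k in keys]
    return pd.DataFrame.from_dict(data, orient="index", columns=keys)


def run_pipeline(cohort_dir, config: PipelineConfig | None = None, out_dir=None) -> dict:
    """Run the full pipeline over a cohort directory; returns the cohort report."""
    cfg = config or PipelineConfig()
    base = os.fspath(cohort_dir)
    with open(os.path.join(base, "manifest.json")) as fh:
        manifest = json.load(fh)
    arms = ArmTable.from_tsv(os.path.join(base, "arms.tsv"))
    sim_cfg = manifest.get("config", {})
    captured_mb = float(sim_cfg.get("captured_mb", cfg.captured_mb))
    cfg = dataclasses.replace(cfg, captured_mb=captured_mb)

    driver_sites = set(load_driver_loci())

    report: dict = {"regions": {}, "patients": {}, "cohort": {}, "errors": []}
    grades: dict[str, str] = {}
    patients_of: dict[str, str] = {}
    purity: dict[str, float] = {}
    as_by_region: dict[str, int] = {}
    burden_by_region: dict[str, float] = {}
    flag1q: dict[str, bool] = {}

    snv_labels: dict[str, str] = {}
    cna_labels: dict[str, str] = {}
    events_by_region_all: dict[str, list[CnaEvent]] = {}

    for pspec in manifest["patients"]:
        pid = pspec["id"]
        region_variants: dict[str, list[Variant]] = {}
        region_rescued: dict[str, list[Variant]] = {}
        region_events: dict[str, list[CnaEvent]] = {}
        per_caller_by_region: dict[str, dict] = {}

        for rspec in pspec["regions"]:
            rid = rspec["id"]
            grades[rid] = rspec["grade"]
            patients_of[rid] = pid
            purity[rid] = float(rspec["purity"])
            rdir = os.path.join(base, "patients", pid, rid)
            try:
                per_caller = _region_variant_calls(rdir, rspec["vcfs"])
                ai = pio.read_ai_table(os.path.join(rdir, "ai.tsv"))
                logr = pio.read_seg_table(os.path.join(rdir, "logr.seg"))
            except (OSError, ValueError) as exc:
                report["errors"].append({"region": rid, "error": str(exc)})
                continue
            per_caller_by_region[rid] = per_caller
            events = overlay_cna(ai, logr, cfg.logr_gain, cfg.logr_loss)
            region_events[rid] = events
            events_by_region_all[rid] = events

        # first pass: stringent consensus per region (panel-free) to build the
        # per-patient shared-site set for targeted rescue
        first_pass: dict[str, dict] = {}
        for rid, per_caller in per_caller_by_region.items():
            first_pass[rid] = harmonize_region(per_caller, cfg, panel=None)
        for rid, per_caller in per_caller_by_region.items():
            shared = {
                v.site
                for other, res in first_pass.items()
                if other != rid
                for v in res["variants"]
            }
            panel = RescuePanel(driver_loci=driver_sites, shared_sites=shared)
            res = harmonize_region(per_caller, cfg, panel=panel)
            region_variants[rid] = res["variants"]
            region_rescued[rid] = res["rescued"]
            burden_by_region[rid] = res["burden"] = mutation_burden(
                res["variants"], cfg.captured_mb
            )
            summary = region_cna_summary(region_events[rid], arms)
            as_by_region[rid] = summary["aneuploidy_score"]
            flag1q[rid] = summary["arm_gain_flag"]
            report["regions"][rid] = {
                "patient": pid,
                "grade": grades[rid],
                "n_variants": len(res["variants"]),
                "n_rescued": len(res["rescued"]),
                "burden": res["burden"],
                "variant_keys": [list(v.key) for v in res["variants"] + res["rescued"]],
                "events": [
                    {
                        "chrom": e.chrom, "start": e.start, "end": e.end,
                        "direction": e.direction, "focal": e.focal,
                    }
                    for e in region_events[rid]
                ],
                **summary,
            }

        # trajectory (needs >= 2 regions)
        patient_grades = {r["id"]: r["grade"] for r in pspec["regions"]}
        snv_label = cna_label = "unclassifiable"
        expansions: list[dict] = []
        if len(region_variants) >= 2:
            vaf = _patient_vaf_matrix(
                {
                    rid: region_variants[rid] + region_rescued[rid]
                    for rid in region_variants
                },
                region_events,
            )
            if vaf.shape[1] > 0:
                clusters = cluster_variants(
                    vaf,
                    purity,
                    presence_threshold=cfg.presence_threshold,
                    merge_distance=cfg.cluster_distance,
                    min_variants=cfg.min_cluster_variants,
                )
                tree = build_snv_tree(
                    clusters,
                    presence_threshold=cfg.presence_threshold,
                    tol=cfg.containment_tol,
                )
                snv_label = classify_topology(
                    tree, patient_grades, presence_threshold=cfg.presence_threshold
                )
                expansions = detect_minor_expansion(tree, patient_grades)
            profiles = arm_state_profiles(
                region_events, arms, min_event_mb=cfg.min_cna_tree_mb
            )
            cna_result = build_cna_tree(profiles, patient_grades)
            cna_label = cna_result.classification
        snv_labels[pid] = snv_label
        cna_labels[pid] = cna_label
        report["patients"][pid] = {
            "snv_topology": snv_label,
            "cna_topology": cna_label,
            "minor_expansions": expansions,
        }

    # ---- transcriptomic subtyping -------------------------------------
    counts_path = os.path.join(base, "expression", "counts.tsv")
    region_subtype: dict[str, str] = {}
    if os.path.exists(counts_path):
        counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
        normalized = normalize_counts(counts)
        tdir = os.path.join(base, "templates")
        templates = {
            os.path.splitext(f)[0]: TemplateSet.from_tsv(os.path.join(tdir, f))
            for f in sorted(os.listdir(tdir))
        }
        replicate_regions = manifest.get("replicate_regions", {})
        subtype_report: dict[str, dict] = {}
        for name, tset in sorted(templates.items()):
            calls = classify_replicates(
                normalized,
                tset,
                n_perm=cfg.n_perm,
                fdr_threshold=cfg.fdr_threshold,
                seed=cfg.seed,
            )
            per_region: dict[str, list] = {}
            for c in calls:
                rid = replicate_regions.get(c.replicate)
                if rid is not None:
                    per_region.setdefault(rid, []).append(c)
            labels = {rid: aggregate_replicates(cs) for rid, cs in per_region.items()}
            subtype_report[name] = {
                "region_labels": labels,
                "switches": class_switches(labels, grades, patients_of),
                "replicates": [
                    {
                        "replicate": c.replicate,
                        "label": c.call,
                        "distance": c.distance,
                        "p": c.p,
                        "fdr": c.fdr,
                    }
                    for c in calls
                ],
            }
        report["subtype"] = subtype_report
        # headline labels: the basal/classical (Moffitt-style) classifier
        headline = "moffitt" if "moffitt" in subtype_report else sorted(subtype_report)[0]
        region_subtype = subtype_report[headline]["region_labels"]

    # ---- cohort statistics --------------------------------------------
    hg_regions = [r for r, g in grades.items() if g == "HG" and r in region_subtype]
    table, excluded = _subtype_table(region_subtype, flag1q, hg_regions)
    tab = ContingencyTable2x2(*table)
    test = exact_2x2(tab) if tab.total else None
    pairs = _lg_hg_pairs(grades, patients_of)
    report["cohort"] = {
        "subtype_1q_table": list(table),
        "subtype_1q_excluded": excluded,
        "subtype_1q_test": dataclasses.asdict(test) if test else None,
        "aneuploidy_by_grade": compare_grades(as_by_region, grades, pairs),
        "burden_by_grade": compare_grades(burden_by_region, grades, pairs),
        "trajectory_agreement": None,
    }
    traj_df, agreement = compare_trajectories(snv_labels, cna_labels)
    report["cohort"]["trajectory_agreement"] = {
        "fraction": agreement,
        "per_patient": traj_df.to_dict(orient="records"),
    }

    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=str)
        rows = [
            {
                "region": rid,
                "patient": r["patient"],
                "grade": r["grade"],
                "burden": r["burden"],
                "aneuploidy_score": r["aneuploidy_score"],
                "flag_1q": r["arm_gain_flag"],
                "subtype": region_subtype.get(rid, ""),
            }
            for rid, r in sorted(report["regions"].items())
        ]
        pd.DataFrame(rows).to_csv(
            os.path.join(out_dir, "regions.tsv"), sep="\t", index=False
        )
    return report


def _subtype_table(labels, flags, hg_regions):
    from .subtype import subtype_cna_table

    sub = {r: labels[r] for r in hg_regions}
    return subtype_cna_table(sub, flags)


def _lg_hg_pairs(grades, patients_of):
    by_patient: dict[str, dict[str, str]] = {}
    for rid, grade in grades.items():
        if grade in ("LG", "HG"):
            by_patient.setdefault(patients_of[rid], {}).setdefault(grade, rid)
    return {
        pid: (d["LG"], d["HG"])
        for pid, d in by_patient.items()
        if "LG" in d and "HG" in d
    }


# ---------------------------------------------------------------------------
# truth comparison (simulated cohorts)
# ---------------------------------------------------------------------------

def score_recovery(report: dict, cohort) -> dict:
    """Compare a pipeline report against a simulated cohort's ground truth."""
    from .subtype import NONCLASSIFIABLE

    n_pat = 0
    topo_ok = 0
    region_rows = []
    sub_total = sub_ok = 0
    for patient in cohort.patients:
        n_pat += 1
        got = report["patients"].get(patient.patient, {}).get("snv_topology")
        topo_ok += got == patient.topology
        for region in patient.regions:
            rep = report["regions"].get(region.region, {})
            truth = region.truth_summary(cohort.arms, cohort.config.captured_mb)
            truth_keys = {tv.key for tv in region.true_variants}
            got_keys = {tuple(k) for k in rep.get("variant_keys", [])}
            got_keys = {(c, int(p), r, a) for c, p, r, a in got_keys}
            truth_events = {
                (e.chrom, e.start, e.end, e.direction) for e in region.true_events
            }
            got_events = {
                (e["chrom"], e["start"], e["end"], e["direction"])
                for e in rep.get("events", [])
            }
            expected_sub = _expected_headline_label(region.subtype)
            got_sub = report.get("subtype", {}).get("moffitt", {})
            got_label = got_sub.get("region_labels", {}).get(region.region)
            if region.grade in ("LG", "HG") and expected_sub != NONCLASSIFIABLE:
                sub_total += 1
                sub_ok += got_label == expected_sub
            region_rows.append(
                {
                    "region": region.region,
                    "variants_exact": got_keys == truth_keys,
                    "recall": (
                        len(got_keys & truth_keys) / len(truth_keys)
                        if truth_keys
                        else 1.0
                    ),
                    "precision": (
                        len(got_keys & truth_keys) / len(got_keys) if got_keys else 1.0
                    ),
                    "events_exact": got_events == truth_events,
                    "as_match": rep.get("aneuploidy_score") == truth["aneuploidy_score"],
                    "flag1q_match": rep.get("arm_gain_flag") == truth["flag_1q"],
                    "subtype_match": got_label == expected_sub,
                }
            )
    df = pd.DataFrame(region_rows)
    return {
        "topology_accuracy": topo_ok / n_pat if n_pat else float("nan"),
        "subtype_accuracy": sub_ok / sub_total if sub_total else float("nan"),
        "regions": df,
        "all_variants_exact": bool(df["variants_exact"].all()) if len(df) else True,
        "all_events_exact": bool(df["events_exact"].all()) if len(df) else True,
        "all_as_match": bool(df["as_match"].all()) if len(df) else True,
        "all_flag1q_match": bool(df["flag1q_match"].all()) if len(df) else True,
        "mean_recall": float(df["recall"].mean()) if len(df) else float("nan"),
        "mean_precision": float(df["precision"].mean()) if len(df) else float("nan"),
    }


def _expected_headline_label(master: str) -> str:
    from .subtype import NONCLASSIFIABLE
    from .synthetic import MASTER_TO_CLASS

    mapped = MASTER_TO_CLASS.get(master, {}).get("moffitt")
    return mapped if mapped is not None else NONCLASSIFIABLE
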