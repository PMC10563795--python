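"""Nearest-template transcriptomic subtyping with permutation significance.

Counts are normalized by median-of-ratios scale factors and log-transformed;
each replicate profile is assigned to the template class with the smallest
correlation distance, with a gene-label permutation p-value and
Benjamini–Hochberg adjustment across replicates.  Replicates whose FDR
exceeds the threshold are nonclassifiable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources as _importlib_resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemplateSet",
    "SubtypeCall",
    "NONCLASSIFIABLE",
    "normalize_counts",
    "ntp_classify",
    "classify_replicates",
    "aggregate_replicates",
    "class_switches",
    "subtype_cna_table",
    "default_templates",
    "bh_adjust",
]

NONCLASSIFIABLE = "nonclassifiable"


class TemplateSet:
    """Named classifier templates: a gene x class matrix of template weights."""

    def __init__(self, name: str, weights: pd.DataFrame):
        if weights.shape[1] < 2:
            raise ValueError("a template set needs at least 2 classes")
        self.name = name
        self.weights = weights.astype(float)

    @property
    def classes(self) -> list[str]:
        return list(self.weights.columns)

    @property
    def genes(self) -> list[str]:
        return list(self.weights.index)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "TemplateSet":
        df = pd.read_csv(path, sep="\t")
        wide = df.pivot(index="gene", columns="class", values="weight")
        if name is None:
            import os

            name = os.path.splitext(os.path.basename(str(path)))[0]
        return cls(name, wide)

    def to_tsv(self, path) -> None:
        long = self.weights.reset_index().melt(
            id_vars="gene", var_name="class", value_name="weight"
        )
        long.rename(columns={"index": "gene"}).to_csv(path, sep="\t", index=False)


def default_templates() -> dict[str, TemplateSet]:
    """The three packaged synthetic classifier template sets."""
    base = _importlib_resources.files("precevo.resources") / "templates"
    return {
        name: TemplateSet.from_tsv(base / f"{name}.tsv", name)
        for name in ("moffitt", "collisson", "bailey")
    }


@dataclass
class SubtypeCall:
    replicate: str
    classifier: str
    label: str  # best template class, regardless of significance
    distance: float
    p: float
    fdr: float = float("nan")
    classifiable: bool = False
    reason: str = ""

    @property
    def call(self) -> str:
        return self.label if self.classifiable else NONCLASSIFIABLE


def normalize_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Median-of-ratios scaling followed by log2(x + 1).

    All-zero samples are dropped with a warning; column order of the
    survivors is preserved.
    """
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=0)
    dead = totals[totals == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping all-zero samples: {dead}")
        counts = counts.drop(columns=dead)
    log = np.log(counts.where(counts > 0))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log_geo_mean = log.mean(axis=1)
    usable = log_geo_mean.notna() & (counts > 0).all(axis=1)
    if not usable.any():
        size_factors = pd.Series(1.0, index=counts.columns)
    else:
        ratios = log.loc[usable].sub(log_geo_mean[usable], axis=0)
        size_factors = np.exp(ratios.median(axis=0))
    return np.log2(counts.div(size_factors, axis=1) + 1.0)


def _pearson_to_templates(values: np.ndarray, templates: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of each profile row against each template column."""
    v = values - values.mean(axis=1, keepdims=True)
    t = templates - templates.mean(axis=0, keepdims=True)
    vn = np.linalg.norm(v, axis=1, keepdims=True)
    tn = np.linalg.norm(t, axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (v @ t) / (vn * tn)


def ntp_classify(
    profile: pd.Series,
    templates: TemplateSet,
    n_perm: int = 1000,
    seed: int = 0,
    min_genes: int = 20,
) -> SubtypeCall:
    """Nearest-template call for a single normalized profile.

    Distance to a class is 1 − Pearson correlation over the template genes
    present in the profile.  The permutation p-value shuffles gene labels
    within the profile: p = (1 + #{perm distance <= observed}) / (n_perm + 1).
    FDR is left NaN here; adjust across replicates with
    :func:`classify_replicates`.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rep = str(profile.name) if profile.name is not None else "profile"
    shared = [g for g in templates.genes if g in profile.index]
    if len(shared) < min_genes:
        return SubtypeCall(
            rep, templates.name, NONCLASSIFIABLE, float("nan"), 1.0,
            classifiable=False, reason="low gene overlap",
        )
    values = profile.loc[shared].to_numpy(dtype=float)
    tmpl = templates.weights.loc[shared].to_numpy(dtype=float)
    if np.allclose(values, values[0]):
        return SubtypeCall(
            rep, templates.name, NONCLASSIFIABLE, float("nan"), 1.0,
            classifiable=False, reason="flat profile",
        )
    corr = _pearson_to_templates(values[None, :], tmpl)[0]
    dist = 1.0 - corr
    best = int(np.nanargmin(dist))
    observed = float(dist[best])

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    perm_corr = _pearson_to_templates(perms, tmpl[:, [best]])[:, 0]
    perm_dist = 1.0 - perm_corr
    p = (1.0 + np.sum(perm_dist <= observed + 1e-12)) / (n_perm + 1.0)
    return SubtypeCall(
        rep, templates.name, templates.classes[best], observed, float(p)
    )


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg adjusted p-values, monotone and capped at 1."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    if n == 0:
        return []
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


def classify_replicates(
    normalized: pd.DataFrame,
    templates: TemplateSet,
    n_perm: int = 1000,
    fdr_threshold: float = 0.05,
    seed: int = 0,
    min_genes: int = 20,
) -> list[SubtypeCall]:
    """Classify every column of a normalized matrix and BH-adjust across them."""
    calls = []
    for i, col in enumerate(normalized.columns):
        calls.append(
            ntp_classify(
                normalized[col], templates, n_perm=n_perm, seed=seed + 7919 * i,
                min_genes=min_genes,
            )
        )
    fdrs = bh_adjust([c.p for c in calls])
    for c, f in zip(calls, fdrs):
        c.fdr = float(f)
        c.classifiable = c.label != NONCLASSIFIABLE and f <= fdr_threshold
    return calls


def aggregate_replicates(calls: Iterable[SubtypeCall]) -> str:
    """Region label by majority vote over classifiable replicates (tie -> nonclassifiable)."""
    votes: dict[str, int] = {}
    for c in calls:
        if c.classifiable:
            votes[c.label] = votes.get(c.label, 0) + 1
    if not votes:
        return NONCLASSIFIABLE
    top = max(votes.values())
    winners = [lab for lab, n in votes.items() if n == top]
    return winners[0] if len(winners) == 1 else NONCLASSIFIABLE


def class_switches(
    region_labels: Mapping[str, str],
    grades: Mapping[str, str],
    patients: Mapping[str, str],
) -> list[dict]:
    """Patients whose LG and HG region labels are classifiable and differ."""
    by_patient: dict[str, dict[str, str]] = {}
    for region, label in region_labels.items():
        pat = patients.get(region)
        grade = grades.get(region)
        if pat is None or grade not in ("LG", "HG"):
            continue
        by_patient.setdefault(pat, {})[grade] = label
    out = []
    for pat in sorted(by_patient):
        labs = by_patient[pat]
        if (
            "LG" in labs
            and "HG" in labs
            and NONCLASSIFIABLE not in (labs["LG"], labs["HG"])
            and labs["LG"] != labs["HG"]
        ):
            out.append({"patient": pat, "lg": labs["LG"], "hg": labs["HG"]})
    return out


def subtype_cna_table(
    labels: Mapping[str, str],
    flags: Mapping[str, bool],
    classical: str = "classical",
    basal: str = "basal",
) -> tuple[tuple[int, int, int, int], list[str]]:
    """2x2 counts (classical∩1q, classical∩no1q, basal∩1q, basal∩no1q).

    Regions with any other label are excluded and listed separately.
    """
    a = b = c = d = 0
    excluded = []
    for region in sorted(labels):
        lab = labels[region]
        flag = bool(flags.get(region, False))
        if lab == classical:
            a += flag
            b += not flag
        elif lab == basal:
            c += flag
            d += not flag
        else:
            excluded.append(region)
    return (a, b, c, d), excluded
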