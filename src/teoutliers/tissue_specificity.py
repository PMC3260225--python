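"""Entropy-based tissue-specificity of Pol-II promoter binding.

For a gene with relative binding strengths p_t over N tissues, the binding
entropy is H = -sum_t p_t log2 p_t (bits). Genes with H > 2 are treated as
ubiquitously bound ("low tissue-specificity"); H <= 2 as tissue-specific
("high tissue-specificity") — with five tissues the uniform profile sits at
log2 5 ~ 2.32, so the threshold sits just below maximal entropy. The tissue
of strongest binding minimizes the categorical specificity
Q_t = H - log2 p_t.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import prop_test, proportion_se

ENTROPY_THRESHOLD = 2.0  # bits; H <= 2 -> tissue-specific
DEFAULT_P_FLOOR = 0.5  # minimum top-tissue fraction for "single-tissue" genes


@dataclass(frozen=True)
class BindingProfile:
    gene_id: str
    tissues: tuple[str, ...]
    p: tuple[float, ...]  # normalized strengths, sum 1
    entropy: float  # H, bits
    q: tuple[float, ...]  # Q_t = H - log2 p_t, +inf where p_t == 0
    ts_class: str  # "high_TS" (tissue-specific) or "low_TS" (ubiquitous)
    top_tissue: str  # argmin Q_t == argmax p_t


def compute_entropy(raw: Mapping[str, float] | pd.Series) -> tuple[np.ndarray, float]:
    """Normalize raw strengths and return (p, H in bits).

    Zero-strength tissues contribute nothing to H (x log x -> 0 limit).
    """
    s = pd.Series(raw, dtype=float)
    if (s < 0).any():
        raise ValueError("binding strengths must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero binding profile")
    p = (s / total).to_numpy()
    nz = p[p > 0]
    return p, float(-(nz * np.log2(nz)).sum())


def classify_ts(entropy: float, threshold: float = ENTROPY_THRESHOLD) -> str:
    """H <= threshold -> "high_TS" (tissue-specific); H > threshold -> "low_TS"."""
    return "high_TS" if entropy <= threshold else "low_TS"


def compute_Q(p: np.ndarray, entropy: float) -> np.ndarray:
    """Categorical tissue-specificity Q_t = H - log2 p_t (+inf at p_t = 0)."""
    with np.errstate(divide="ignore"):
        return np.where(p > 0, entropy - np.log2(np.where(p > 0, p, 1.0)), np.inf)


def binding_profile(gene_id: str, raw: Mapping[str, float] | pd.Series) -> BindingProfile:
    """Full binding profile for one gene."""
    s = pd.Series(raw, dtype=float)
    p, h = compute_entropy(s)
    q = compute_Q(p, h)
    # argmin Q == argmax p; ties broken by tissue-name sort
    order = sorted(range(len(p)), key=lambda i: (q[i], s.index[i]))
    return BindingProfile(
        gene_id=gene_id,
        tissues=tuple(s.index),
        p=tuple(float(x) for x in p),
        entropy=h,
        q=tuple(float(x) for x in q),
        ts_class=classify_ts(h),
        top_tissue=str(s.index[order[0]]),
    )


def profile_table(binding: pd.DataFrame, threshold: float = ENTROPY_THRESHOLD) -> pd.DataFrame:
    """Vectorized profile summary for a whole binding table.

    Returns a DataFrame indexed by gene_id with columns ``entropy``,
    ``ts_class``, ``top_tissue`` and ``p_max``.
    """
    values = binding.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("binding strengths must be non-negative")
    totals = values.sum(axis=1)
    if (totals <= 0).any():
        bad = binding.index[totals <= 0][0]
        raise ValueError(f"all-zero binding profile for {bad!r}")
    p = values / totals[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = -terms.sum(axis=1)
    # ties at the max broken by tissue-name sort: argmax over name-sorted cols
    name_order = np.argsort(binding.columns)
    top_idx = name_order[np.argmax(p[:, name_order], axis=1)]
    return pd.DataFrame(
        {
            "entropy": h,
            "ts_class": np.where(h <= threshold, "high_TS", "low_TS"),
            "top_tissue": binding.columns.to_numpy()[top_idx],
            "p_max": p.max(axis=1),
        },
        index=binding.index,
    )


def single_tissue_genes(
    profiles: pd.DataFrame, p_floor: float = DEFAULT_P_FLOOR
) -> pd.DataFrame:
    """Genes with strong binding in only one tissue.

    Operationalized as tissue-specific (high_TS) genes whose top tissue
    takes at least ``p_floor`` of the total binding strength.
    """
    return profiles[(profiles["ts_class"] == "high_TS") & (profiles["p_max"] >= p_floor)]


def single_tissue_composition(
    gene_sets: Mapping[str, Iterable[str]],
    profiles: pd.DataFrame,
    tissues: Iterable[str],
    p_floor: float = DEFAULT_P_FLOOR,
) -> pd.DataFrame:
    """Per-set tissue-type fractions of single-tissue genes (rows sum to 1)."""
    single = single_tissue_genes(profiles, p_floor)
    tissues = list(tissues)
    rows = {}
    for name, ids in gene_sets.items():
        sub = single.loc[single.index.intersection(list(ids))]
        if len(sub) == 0:
            raise ValueError(f"gene set {name!r} has no single-tissue genes")
        counts = sub["top_tissue"].value_counts()
        rows[name] = {t: counts.get(t, 0) / len(sub) for t in tissues}
        rows[name]["n"] = len(sub)
    return pd.DataFrame.from_dict(rows, orient="index", columns=tissues + ["n"])


def ts_enrichment(
    gene_sets: Mapping[str, Iterable[str]],
    background_ids: Iterable[str],
    profiles: pd.DataFrame,
    continuity: bool = True,
) -> pd.DataFrame:
    """High-TS fraction per gene set, compared with the genomic background.

    One row per set plus a ``background`` row; fractions come with a
    sqrt(p(1-p)/n) standard error and a two-proportion test against the
    background.
    """
    bg = profiles.loc[profiles.index.intersection(list(background_ids))]
    if len(bg) == 0:
        raise ValueError("empty background")
    bg_x = int((bg["ts_class"] == "high_TS").sum())
    bg_n = len(bg)
    rows = {}
    for name, ids in gene_sets.items():
        sub = profiles.loc[profiles.index.intersection(list(ids))]
        if len(sub) == 0:
            raise ValueError(f"gene set {name!r} has no profiled genes")
        x, n = int((sub["ts_class"] == "high_TS").sum()), len(sub)
        report = prop_test(x, n, bg_x, bg_n, continuity=continuity)
        rows[name] = {
            "high_ts_fraction": x / n,
            "se": proportion_se(x / n, n),
            "n": n,
            "p_vs_background": report.p,
        }
    rows["background"] = {
        "high_ts_fraction": bg_x / bg_n,
        "se": proportion_se(bg_x / bg_n, bg_n),
        "n": bg_n,
        "p_vs_background": float("nan"),
    }
    return pd.DataFrame.from_dict(rows, orient="index")
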