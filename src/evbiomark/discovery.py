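"""The tumor-origin intersection filter and per-marker diagnostic metrics.

A circulating RNA is a credible *tumor-derived* biomarker when it is both
elevated in patients at diagnosis relative to cancer-free controls and
reduced again once the tumor is surgically removed.  Candidates are the
intersection of the two direction-filtered differential-expression calls.
Each candidate is then scored as a standalone diagnostic: detection
sensitivity/specificity (raw-count presence/absence) and the Mann–Whitney
concordance AUC of its normalized abundance between patients and controls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .countmatrix import CountMatrix, SampleTable
from .diffexpr import normalize_within_biotype


class DiscoveryError(ValueError):
    pass


def intersect_candidates(
    up_in_preop_vs_hc: pd.DataFrame, down_postop: pd.DataFrame
) -> pd.DataFrame:
    """Intersect the two significance calls into the candidate table.

    Parameters
    ----------
    up_in_preop_vs_hc
        Rows of the PreOp-vs-HC result already filtered to significant
        *up* features (e.g. ``call_significant(...)`` with direction up).
    down_postop
        Rows of the PreOp-vs-PostOp result filtered to features that are
        significantly *higher in PreOp* (i.e. that drop after surgery).

    Returns a DataFrame indexed by feature_id carrying both contrasts'
    log2FC and adjusted p.
    """
    shared = up_in_preop_vs_hc.index.intersection(down_postop.index)
    a = up_in_preop_vs_hc.loc[shared]
    b = down_postop.loc[shared]
    return pd.DataFrame(
        {
            "biotype": a["biotype"],
            "log2FC_preop_vs_hc": a["log2FC"],
            "adj_p_preop_vs_hc": a["adj_p"],
            "log2FC_preop_vs_postop": b["log2FC"],
            "adj_p_preop_vs_postop": b["adj_p"],
        },
        index=shared,
    ).sort_index()


def detection_metrics(
    feature_id: str,
    cm: CountMatrix,
    samples: SampleTable,
    detection_threshold: int = 1,
) -> tuple[float, float]:
    """Presence/absence sensitivity and specificity of one candidate.

    Sensitivity is the fraction of PreOp samples in which the feature is
    detected (raw count >= ``detection_threshold``); specificity the
    fraction of HC samples in which it is not.
    """
    if feature_id not in cm.counts.index:
        raise DiscoveryError(f"unknown feature {feature_id!r}")
    if detection_threshold < 1:
        raise DiscoveryError("detection_threshold must be >= 1 read")
    preop = cm.counts.loc[feature_id, samples.samples_in_group("PreOp")]
    hc = cm.counts.loc[feature_id, samples.samples_in_group("HC")]
    sensitivity = float((preop >= detection_threshold).mean())
    specificity = float((hc < detection_threshold).mean())
    return sensitivity, specificity


def concordance_auc(cases: np.ndarray, controls: np.ndarray) -> float:
    """Mann–Whitney concordance: P(case score > control score) + 0.5 ties."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise DiscoveryError("both groups must be non-empty for AUC")
    u = stats.mannwhitneyu(cases, controls, alternative="two-sided").statistic
    return float(u / (len(cases) * len(controls)))


def marker_auc(
    feature_id: str,
    cm: CountMatrix,
    samples: SampleTable,
    normalized: pd.DataFrame | None = None,
) -> float:
    """Single-marker AUC (PreOp vs HC) on within-biotype normalized abundance."""
    if feature_id not in cm.counts.index:
        raise DiscoveryError(f"unknown feature {feature_id!r}")
    if normalized is None:
        normalized, _ = normalize_within_biotype(cm)
    preop = normalized.loc[feature_id, samples.samples_in_group("PreOp")].to_numpy()
    hc = normalized.loc[feature_id, samples.samples_in_group("HC")].to_numpy()
    preop = preop[~np.isnan(preop)]
    hc = hc[~np.isnan(hc)]
    return concordance_auc(preop, hc)


def annotate_candidates(
    candidates: pd.DataFrame,
    cm: CountMatrix,
    samples: SampleTable,
    detection_threshold: int = 1,
) -> pd.DataFrame:
    """Add sensitivity, specificity and single-marker AUC to a candidate table."""
    normalized, _ = normalize_within_biotype(cm)
    sens, spec, aucs = [], [], []
    for fid in candidates.index:
        se, sp = detection_metrics(fid, cm, samples, detection_threshold)
        sens.append(se)
        spec.append(sp)
        aucs.append(marker_auc(fid, cm, samples, normalized=normalized))
    out = candidates.copy()
    out["sensitivity"] = sens
    out["specificity"] = spec
    out["auc"] = aucs
    return out
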