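"""Clinical-status association and receptor-status prediction panels.

Patients are dichotomized on immunohistochemistry-derived variables
(estrogen/progesterone receptor, HER2 score, grade, Ki-67 proliferation
index, ...), pre-treatment marker abundances are compared between the two
patient groups with rank-sum tests, and receptor-status prediction panels
are built with the same backward-elimination + LOOCV machinery as the
diagnostic model.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .composition import _wilcoxon_rank_sum
from .countmatrix import CountMatrix, SampleTable
from .diffexpr import bh_adjust, normalize_within_biotype
from .panelmodel import PanelModel, build_panel, marker_design

logger = logging.getLogger(__name__)


class ClinicalError(ValueError):
    pass


#: Default dichotomization rules. HER2 positivity defaults to IHC score 3
#: only (score 2 lacks in-situ-hybridization confirmation); the "2+3" rule
#: treats scores 2 and 3 as positive.
DICHOTOMY_RULES = {
    "ER": {"kind": "binary", "positive": "positive"},
    "PR": {"kind": "binary", "positive": "positive"},
    "HER2_IHC": {"kind": "her2", "positive_scores": (3,)},
    "grade": {"kind": "binary", "positive": 3},
    "T_stage": {"kind": "threshold", "positive_min": 3},
    "TNBC": {"kind": "binary", "positive": "yes"},
    "E_cadherin": {"kind": "binary", "positive": "positive"},
    "Ki67": {"kind": "binary", "positive": ">14%"},
}


def dichotomize(
    clinical: pd.DataFrame,
    variable: str,
    her2_rule: str = "3",
) -> pd.Series:
    """Binary labels (1/0) per patient for one clinical variable.

    ``clinical`` is a per-patient table (index = subject).  Patients with a
    missing value are excluded (logged).  ``her2_rule`` chooses which IHC
    scores count as HER2-positive: ``"3"`` (default) or ``"2+3"``.
    """
    if variable not in DICHOTOMY_RULES:
        raise ClinicalError(
            f"no dichotomization rule for {variable!r}; known: {sorted(DICHOTOMY_RULES)}"
        )
    if variable not in clinical.columns:
        raise ClinicalError(f"variable {variable!r} not present in clinical table")
    col = clinical[variable]
    missing = col.isna()
    if missing.any():
        logger.info(
            "excluding %d patients with missing %s: %s",
            int(missing.sum()),
            variable,
            ", ".join(map(str, clinical.index[missing])),
        )
        col = col[~missing]
    rule = DICHOTOMY_RULES[variable]
    if rule["kind"] == "her2":
        pos_scores = (2, 3) if her2_rule == "2+3" else (3,)
        labels = col.astype(int).isin(pos_scores)
    elif rule["kind"] == "threshold":
        labels = col.astype(int) >= rule["positive_min"]
    else:
        labels = col == rule["positive"]
    return labels.astype(int)


def associate_markers(
    cm: CountMatrix,
    samples: SampleTable,
    labels: pd.Series,
    feature_ids=None,
    min_group: int = 3,
) -> pd.DataFrame:
    """Rank-sum association of pre-treatment marker levels with a binary
    clinical status.

    Only PreOp samples enter; ``labels`` is indexed by patient subject.
    Returns per-feature delta of group means, raw p and BH-adjusted p.
    """
    preop = samples.table[samples.table["group"] == "PreOp"]
    subj_to_sample = dict(zip(preop["subject"], preop["sample_id"]))
    common = [s for s in labels.index if s in subj_to_sample]
    y = labels.loc[common].to_numpy()
    if min(int(y.sum()), int(len(y) - y.sum())) < min_group:
        raise ClinicalError(
            f"a label group has fewer than {min_group} patients; skipping variable"
        )
    sample_ids = [subj_to_sample[s] for s in common]
    normalized, _ = normalize_within_biotype(cm)
    if feature_ids is None:
        feature_ids = cm.counts.index
    rows = []
    for fid in feature_ids:
        vals = normalized.loc[fid, sample_ids].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        a = vals[ok & (y == 1)]
        b = vals[ok & (y == 0)]
        if len(a) < min_group or len(b) < min_group:
            continue
        if np.ptp(np.concatenate([a, b])) == 0.0:
            p = 1.0
        else:
            p = _wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "feature_id": fid,
                "biotype": cm.biotypes[fid],
                "mean_positive": a.mean(),
                "mean_negative": b.mean(),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("feature_id")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    return out


def receptor_status_model(
    cm: CountMatrix,
    samples: SampleTable,
    labels: pd.Series,
    candidate_ids,
    criterion: str = "aic",
    min_class: int = 5,
) -> PanelModel:
    """Backward-elimination logistic panel predicting a receptor status.

    Units are patients (their PreOp sample); delegates to the panel
    machinery used for the case/control diagnostic model.
    """
    preop = samples.table[samples.table["group"] == "PreOp"]
    subj_to_sample = dict(zip(preop["subject"], preop["sample_id"]))
    common = [s for s in labels.index if s in subj_to_sample]
    y = labels.loc[common].to_numpy()
    if min(int(y.sum()), int(len(y) - y.sum())) < min_class:
        raise ClinicalError(f"each status class needs >= {min_class} patients")
    sample_ids = [subj_to_sample[s] for s in common]
    normalized, _ = normalize_within_biotype(cm)
    X = marker_design(normalized, candidate_ids, sample_ids)
    # drop markers invisible in the PreOp stratum (constant columns)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    if not keep:
        raise ClinicalError("no candidate marker varies across PreOp samples")
    return build_panel(X[keep], y, criterion=criterion)
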