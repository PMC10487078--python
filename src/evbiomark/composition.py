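"""Per-sample RNA biotype composition and group comparison.

The fraction of assigned reads falling in each biotype is itself a
biomarker-bearing signal: in breast-cancer plasma EVs the shares of
miRNA, snRNA, snoRNA and tRNA fragments rise while the lncRNA share
falls relative to healthy controls.  Fractions are compared between
groups with Wilcoxon tests (rank-sum unpaired, signed-rank paired) and
Benjamini–Hochberg correction across biotypes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import BIOTYPES
from .countmatrix import CountMatrix, SampleTable
from .diffexpr import bh_adjust


class CompositionError(ValueError):
    pass


def biotype_fractions(cm: CountMatrix) -> pd.DataFrame:
    """Fraction of each sample's assigned reads per biotype.

    Returns a biotype x sample DataFrame whose columns each sum to 1.
    """
    totals_by_biotype = cm.biotype_totals().reindex(list(BIOTYPES), fill_value=0)
    sample_totals = totals_by_biotype.sum(axis=0)
    zero = sample_totals[sample_totals == 0]
    if len(zero):
        raise CompositionError(
            f"samples with zero assigned reads: {', '.join(map(str, zero.index))}"
        )
    return totals_by_biotype / sample_totals


def _wilcoxon_rank_sum(x: np.ndarray, y: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided rank-sum p. Exact null when both groups are small and
    tie-free; tie-corrected normal approximation with continuity otherwise."""
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not has_ties and max(len(x), len(y)) <= exact_max_n:
        return float(stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue)
    return float(
        stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def _wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    d = x - y
    if np.all(d == 0):
        return 1.0
    mode = "exact" if len(d) <= 25 and len(np.unique(np.abs(d[d != 0]))) == np.sum(d != 0) else "approx"
    return float(stats.wilcoxon(x, y, alternative="two-sided", mode=mode).pvalue)


def compare_fractions(
    fractions: pd.DataFrame,
    samples: SampleTable,
    group_a: str,
    group_b: str,
    paired: bool = False,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare biotype fractions between two sample groups.

    Parameters
    ----------
    fractions
        Output of :func:`biotype_fractions` (biotype x sample).
    group_a, group_b
        Group labels from the sample sheet (e.g. ``PreOp`` vs ``HC``).
    paired
        Use the signed-rank test on subject-matched samples (e.g. PreOp vs
        PostOp); requires both groups to cover the same subjects.

    Returns
    -------
    DataFrame indexed by biotype with group means, the direction of change
    (mean_a - mean_b), raw p, BH-adjusted p (across the biotypes tested)
    and a significance flag at adjusted p < alpha.
    """
    ids_a = samples.samples_in_group(group_a)
    ids_b = samples.samples_in_group(group_b)
    if not ids_a or not ids_b:
        raise CompositionError(f"empty group among {group_a!r}, {group_b!r}")
    if paired:
        subj_a = samples.subjects_for(ids_a)
        subj_b = samples.subjects_for(ids_b)
        if set(subj_a) != set(subj_b) or len(ids_a) != len(ids_b):
            raise CompositionError(
                f"paired comparison requested but {group_a} and {group_b} do not "
                "cover the same subjects"
            )
        order = {s: i for i, s in enumerate(subj_a)}
        ids_b = [ids_b[i] for i in np.argsort([order[s] for s in subj_b])]

    rows = []
    for biotype in fractions.index:
        a = fractions.loc[biotype, ids_a].to_numpy(dtype=float)
        b = fractions.loc[biotype, ids_b].to_numpy(dtype=float)
        p = _wilcoxon_signed_rank(a, b) if paired else _wilcoxon_rank_sum(a, b)
        rows.append(
            {
                "biotype": biotype,
                f"mean_{group_a}": a.mean(),
                f"mean_{group_b}": b.mean(),
                "delta": a.mean() - b.mean(),
                "p": p,
            }
        )
    out = pd.DataFrame(rows).set_index("biotype")
    out["adj_p"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["adj_p"] < alpha
    return out
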