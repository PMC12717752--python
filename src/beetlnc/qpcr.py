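"""Relative qPCR expression by the 2^-ddCt method.

Target Ct values are normalised per sample against the arithmetic mean of the
reference-gene Cts (equivalent to geometric-mean normalisation of linear
quantities); ddCt compares each treatment replicate's dCt to the calibrator
condition's mean dCt, and relative expression is 2^-ddCt (amplification
efficiency fixed at 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import ValidationError


@dataclass
class RelExpr:
    gene: str
    treatment: str
    calibrator: str
    per_replicate_rel: np.ndarray
    ddct_mean: float

    @property
    def rel_mean(self) -> float:
        return float(self.per_replicate_rel.mean())

    @property
    def rel_sd(self) -> float:
        return float(self.per_replicate_rel.std(ddof=1)) if len(self.per_replicate_rel) > 1 else 0.0


def delta_ct(target_ct: float, reference_cts) -> float:
    refs = np.asarray(list(reference_cts), dtype=float)
    if refs.size == 0:
        raise ValidationError("empty reference Ct list")
    if not (math.isfinite(target_ct) and np.all(np.isfinite(refs))):
        raise ValidationError("non-finite Ct")
    return float(target_ct - refs.mean())


def _sample_dcts(rows: pd.DataFrame, gene: str) -> np.ndarray:
    """Per-sample dCt for one gene within one condition's rows."""
    dcts = []
    for sample, grp in rows.groupby("sample", sort=True):
        refs = grp.loc[grp["is_reference"], "ct"]
        tgt = grp.loc[(grp["gene"] == gene) & ~grp["is_reference"], "ct"]
        if tgt.empty:
            continue
        if refs.empty:
            raise ValidationError(f"sample {sample!r}: no reference Ct")
        dcts.append(delta_ct(float(tgt.iloc[0]), refs.to_numpy()))
    if not dcts:
        raise ValidationError(f"gene {gene!r}: no target Ct rows")
    return np.asarray(dcts)


def ddct_relative(
    ct_table: pd.DataFrame,
    gene: str,
    treatment: str = "LN",
    calibrator: str = "CV",
) -> RelExpr:
    """Relative expression of ``gene`` in treatment vs calibrator condition."""
    for cond in (treatment, calibrator):
        if not (ct_table["condition"] == cond).any():
            raise ValidationError(f"condition {cond!r} missing from Ct table")
    treat_dct = _sample_dcts(ct_table[ct_table["condition"] == treatment], gene)
    calib_dct = _sample_dcts(ct_table[ct_table["condition"] == calibrator], gene)
    ddct = treat_dct - calib_dct.mean()
    return RelExpr(gene, treatment, calibrator, 2.0 ** (-ddct), float(ddct.mean()))


def relative_expression_table(
    ct_table: pd.DataFrame, treatment: str = "LN", calibrator: str = "CV"
) -> pd.DataFrame:
    genes = sorted(ct_table.loc[~ct_table["is_reference"], "gene"].unique())
    rows = []
    for g in genes:
        rel = ddct_relative(ct_table, g, treatment, calibrator)
        rows.append(
            {
                "gene": g,
                "rel_mean": rel.rel_mean,
                "rel_sd": rel.rel_sd,
                "ddct_mean": rel.ddct_mean,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "rel_mean", "rel_sd", "ddct_mean"])


def concordance(rel_table: pd.DataFrame, de_results: pd.DataFrame) -> pd.DataFrame:
    """Per-gene agreement between qPCR direction and the RNA-seq DE call.

    agree / disagree when sign(log2 rel) matches / opposes an up/down call;
    ``indeterminate`` at rel exactly 1; ``not_comparable`` for ns DE calls.
    """
    de = de_results.set_index("feature")
    rows = []
    for _, r in rel_table.iterrows():
        gene = r["gene"]
        if gene not in de.index:
            continue
        call = de.loc[gene, "call"]
        if call == "ns":
            flag = "not_comparable"
        elif r["rel_mean"] == 1.0:
            flag = "indeterminate"
        else:
            qdir = "up" if r["rel_mean"] > 1.0 else "down"
            flag = "agree" if qdir == call else "disagree"
        rows.append({"gene": gene, "rel_mean": r["rel_mean"], "de_call": call, "flag": flag})
    return pd.DataFrame(rows, columns=["gene", "rel_mean", "de_call", "flag"])
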