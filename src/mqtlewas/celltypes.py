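"""Reference-based deconvolution of blood cell-type proportions.

A bulk methylation profile over a set of discriminating CpGs is modelled
as a convex mixture of cell-type reference profiles: the proportions
minimize ||y - R p||^2 subject to p >= 0 and sum(p) = 1.  The seven
classes are CD8 T, CD4 T, NK, B cells, monocytes, granulocytes and
nucleated red blood cells (cord-blood composition).  The EWAS stage
consumes six of the seven as covariates — granulocytes, the dominant
remainder, are dropped to avoid exact collinearity with the intercept.

The simplex-constrained least squares is solved as a nonnegative least
squares on a penalty-augmented system (one extra equation sum(p) = 1 with
a large weight) followed by exact renormalization onto the simplex; the
solve is deterministic and recovers noiseless mixtures to machine-level
accuracy.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io_formats import CELL_CLASSES

_SUM_PENALTY = 1e6


def validate_reference(reference: pd.DataFrame) -> pd.DataFrame:
    """Check the reference matrix contract (CpGs x 7 classes, betas in [0,1])."""
    missing = [c for c in CELL_CLASSES if c not in reference.columns]
    if missing:
        raise ValueError(f"reference missing cell classes: {missing}")
    ref = reference[list(CELL_CLASSES)]
    vals = ref.to_numpy(float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("reference betas outside [0, 1]")
    if len(ref) < 50:
        raise ValueError("reference needs at least 50 CpGs")
    if not np.isfinite(np.linalg.cond(vals)):
        raise ValueError("reference class columns are not distinguishable")
    return ref


def estimate_proportions(sample_betas: np.ndarray | pd.Series,
                         reference: pd.DataFrame,
                         min_overlap: float = 0.9) -> pd.Series:
    """Cell proportions of one sample by constrained projection.

    ``sample_betas`` is the sample's methylation over the reference CpGs;
    when given as a Series it is matched to the reference index and at
    least ``min_overlap`` of reference CpGs must be present.
    """
    ref = validate_reference(reference)
    if isinstance(sample_betas, pd.Series):
        present = ref.index.intersection(sample_betas.index)
        overlap = len(present) / len(ref)
        if overlap < min_overlap:
            raise ValueError(
                f"only {100 * overlap:.1f}% of reference CpGs present "
                f"(need >= {100 * min_overlap:.0f}%)")
        y = sample_betas.loc[present].to_numpy(float)
        R = ref.loc[present].to_numpy(float)
    else:
        y = np.asarray(sample_betas, dtype=float)
        if len(y) != len(ref):
            raise ValueError("beta vector length does not match reference")
        R = ref.to_numpy(float)
    ok = ~np.isnan(y)
    if ok.mean() < min_overlap:
        raise ValueError(f"only {100 * ok.mean():.1f}% of reference CpGs "
                         "non-missing")
    A = np.vstack([R[ok], _SUM_PENALTY * np.ones((1, R.shape[1]))])
    b = np.concatenate([y[ok], [_SUM_PENALTY]])
    p, _ = nnls(A, b)
    total = p.sum()
    if total <= 0:
        raise ValueError("deconvolution degenerate: all proportions zero")
    return pd.Series(p / total, index=list(CELL_CLASSES))


def estimate_proportions_matrix(betas: pd.DataFrame,
                                reference: pd.DataFrame) -> pd.DataFrame:
    """Per-sample deconvolution for a samples x reference-CpGs frame."""
    rows = {s: estimate_proportions(betas.loc[s], reference)
            for s in betas.index}
    return pd.DataFrame(rows).T


def make_covariates(proportions: pd.DataFrame | pd.Series) -> pd.DataFrame:
    """Drop the granulocyte column; fixed order CD8T, CD4T, NK, Bcell, Mono, nRBC."""
    order = [c for c in CELL_CLASSES if c != "Gran"]
    if isinstance(proportions, pd.Series):
        proportions = proportions.to_frame().T
    missing = [c for c in order if c not in proportions.columns]
    if missing:
        raise ValueError(f"missing cell classes: {missing}")
    out = proportions[order].copy()
    out.columns = [f"cell_{c}" for c in order]
    return out
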