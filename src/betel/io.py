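"""CSV schemas for the two sampling settings.

Design setting: columns ``R`` (0/1 selection indicator), ``Y`` (outcome,
blank when R=0) and ``pi`` (known sampling probability in (0, 1], blank
when R=0).

Observational setting: columns ``R``, ``Y`` (blank when R=0) and fully
observed covariates ``W1..Wk`` (or any user-named columns).

Blank cells (missing markers) are the only legal representation of data
unobserved because R=0; a zero there is a schema violation.  Validation is
strict so that unobserved fields can never silently enter arithmetic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "validate_design_frame",
    "validate_obs_frame",
    "load_design_csv",
    "load_obs_csv",
]


def _check_selection(df: pd.DataFrame) -> np.ndarray:
    if "R" not in df.columns:
        raise ValidationError("missing required column 'R'")
    r = df["R"].to_numpy()
    if not np.isin(r, (0, 1)).all():
        raise ValidationError("column 'R' must contain only 0 and 1")
    return r.astype(int)


def validate_design_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a design-setting frame (R, Y, pi); returns a clean copy."""
    for col in ("Y", "pi"):
        if col not in df.columns:
            raise ValidationError(f"missing required column '{col}'")
    df = df.copy()
    r = _check_selection(df)
    df["R"] = r
    sel = r == 1
    y = pd.to_numeric(df["Y"], errors="coerce")
    pi = pd.to_numeric(df["pi"], errors="coerce")
    if y[sel].isna().any():
        raise ValidationError("Y must be present for every record with R=1")
    if pi[sel].isna().any():
        raise ValidationError("pi must be present for every record with R=1")
    if (~y[~sel].isna()).any() or (~pi[~sel].isna()).any():
        raise ValidationError(
            "Y and pi must be blank for records with R=0 (unobserved fields "
            "are masked, not zero-filled)"
        )
    obs_pi = pi[sel].to_numpy(float)
    if np.any(obs_pi <= 0.0) or np.any(obs_pi > 1.0):
        raise ValidationError("observed sampling probabilities must lie in (0, 1]")
    if sel.sum() == 0:
        raise ValidationError("no selected records (all R=0)")
    df["Y"], df["pi"] = y, pi
    return df


def validate_obs_frame(df: pd.DataFrame, w_cols=None) -> tuple[pd.DataFrame, list]:
    """Validate an observational frame; returns (clean copy, covariate cols)."""
    if "Y" not in df.columns:
        raise ValidationError("missing required column 'Y'")
    if w_cols is None:
        w_cols = [c for c in df.columns if c not in ("R", "Y")]
    if not w_cols:
        raise ValidationError("no covariate columns found")
    missing = [c for c in w_cols if c not in df.columns]
    if missing:
        raise ValidationError(f"missing covariate columns: {missing}")
    df = df.copy()
    r = _check_selection(df)
    df["R"] = r
    sel = r == 1
    y = pd.to_numeric(df["Y"], errors="coerce")
    if y[sel].isna().any():
        raise ValidationError("Y must be present for every record with R=1")
    if (~y[~sel].isna()).any():
        raise ValidationError("Y must be blank for records with R=0")
    for c in w_cols:
        w = pd.to_numeric(df[c], errors="coerce")
        if w.isna().any() or not np.isfinite(w.to_numpy(float)).all():
            raise ValidationError(
                f"covariate column '{c}' must be fully observed and finite"
            )
        df[c] = w
    df["Y"] = y
    return df, list(w_cols)


def load_design_csv(path) -> pd.DataFrame:
    return validate_design_frame(pd.read_csv(path))


def load_obs_csv(path, w_cols=None):
    return validate_obs_frame(pd.read_csv(path), w_cols)


def masked_outcome(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (r, y_filled) with y zero-filled ONLY where R=0.

    The fill value never reaches any estimate because every use multiplies
    by R first; it exists to keep NaN out of vectorized arithmetic.
    """
    r = df["R"].to_numpy(float)
    y = np.where(r == 1, df["Y"].to_numpy(float), 0.0)
    return r, y
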