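"""Per-organ descriptor matrices: one row per (animal, stage), columns
A<band>/W<band>/F<band> for that organ's retained bands.

Area, width and frequency live on wildly different scales (counts*cm^-1 vs
cm^-1 vs thousands of cm^-1), so the matrix is autoscaled (unit variance,
zero mean) before any multivariate modelling; missing descriptors (an animal
that does not present a band at a stage) are imputed at the column mean,
i.e. zero after scaling, which is neutral under centred PLS.
"""

from __future__ import annotations

import re
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

VARIABLES = ("A", "W", "F")

_DESCRIPTOR_RE = re.compile(r"^([AWF])(\d+(?:\.\d+)?)$")


def descriptor_name(variable: str, band: str) -> str:
    if variable not in VARIABLES:
        raise ValueError(f"variable must be one of {VARIABLES}")
    return f"{variable}{band}"


def parse_descriptor(name: str) -> tuple[str, str]:
    """Inverse of :func:`descriptor_name`: 'A1409' -> ('A', '1409')."""
    m = _DESCRIPTOR_RE.match(name)
    if not m:
        raise ValueError(f"not a descriptor name: {name!r}")
    return m.group(1), m.group(2)


def build_features(
    labelled_components: pd.DataFrame,
    retained: dict[str, list[str]],
    organ: str,
    manifest: pd.DataFrame,
    collapse: str = "max_area",
) -> pd.DataFrame:
    """Build the (animal, stage) x descriptor matrix for one organ.

    For each (animal, stage, band): among the animal's replicate components
    of that band, take the one with the largest area (strongest detection;
    ``collapse="mean"`` averages over replicates instead).  Bands the animal
    does not present are left as NaN.  Rows cover every (animal, stage) the
    manifest records for the organ, in sorted order; the first two columns
    are ``animal_id`` and ``stage_hpf``.
    """
    bands = retained.get(organ, [])
    if not bands:
        raise ValueError(f"no retained bands for organ {organ!r}")
    if collapse not in ("max_area", "mean"):
        raise ValueError("collapse must be 'max_area' or 'mean'")
    obs = (
        manifest.loc[manifest["organ"] == organ, ["animal_id", "stage_hpf"]]
        .drop_duplicates()
        .sort_values(["animal_id", "stage_hpf"], kind="stable")
        .reset_index(drop=True)
    )
    comp = labelled_components[
        (labelled_components["organ"] == organ)
        & labelled_components["band"].isin(bands)
    ]
    cols = [descriptor_name(v, b) for b in bands for v in VARIABLES]
    out = pd.DataFrame(np.nan, index=obs.index, columns=cols)
    picked = {}
    for (animal, stage, band), grp in comp.groupby(["animal_id", "stage_hpf", "band"]):
        grp = grp.sort_values(["file", "component_index"], kind="stable")
        if collapse == "max_area":
            row = grp.loc[grp["A"].idxmax()]
            picked[(animal, stage, band)] = (row["A"], row["W"], row["F"])
        else:
            picked[(animal, stage, band)] = (
                grp["A"].mean(),
                grp["W"].mean(),
                grp["F"].mean(),
            )
    for i, (animal, stage) in enumerate(zip(obs["animal_id"], obs["stage_hpf"])):
        for band in bands:
            vals = picked.get((animal, stage, band))
            if vals is None:
                continue
            a, w, f = vals
            out.loc[i, descriptor_name("A", band)] = a
            out.loc[i, descriptor_name("W", band)] = w
            out.loc[i, descriptor_name("F", band)] = f
    # band-then-variable order: A980, W980, F980, A1002, ...
    ordered = [descriptor_name(v, b) for b in bands for v in ("A", "W", "F")]
    out = out[ordered]
    return pd.concat([obs, out], axis=1)


class FeatureScaler(TransformerMixin, BaseEstimator):
    """Autoscaling (unit variance) with NaN-aware statistics.

    Column means and sample standard deviations (ddof=1) are computed over
    non-missing entries; after scaling, missing entries are imputed with 0
    (the column mean).  Zero-variance columns are dropped with a warning.
    ``inverse_transform`` restores the original scale (imputed entries come
    back as the column mean).
    """

    def __init__(self, ddof: int = 1):
        self.ddof = ddof

    def fit(self, X, y=None):
        X = self._as_frame(X)
        mean = X.mean(axis=0, skipna=True)
        std = X.std(axis=0, ddof=self.ddof, skipna=True)
        n_ok = X.notna().sum(axis=0)
        if (n_ok < 2).any():
            bad = list(X.columns[n_ok < 2])
            raise ValueError(f"columns with < 2 non-missing values: {bad}")
        keep = std > 1e-12
        dropped = list(X.columns[~keep])
        if dropped:
            warnings.warn(
                f"dropping zero-variance column(s): {', '.join(map(str, dropped))}",
                stacklevel=2,
            )
        self.columns_ = list(X.columns[keep])
        self.dropped_ = dropped
        self.mean_ = mean[keep].to_numpy()
        self.scale_ = std[keep].to_numpy()
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = self._as_frame(X)[self.columns_]
        Z = (X - self.mean_) / self.scale_
        return Z.fillna(0.0)

    def inverse_transform(self, Z):
        check_is_fitted(self, "mean_")
        Z = self._as_frame(Z)[self.columns_]
        return Z * self.scale_ + self.mean_

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X.astype(float)
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])


def autoscale(matrix: pd.DataFrame) -> tuple[pd.DataFrame, FeatureScaler]:
    """Autoscale the descriptor columns of a feature matrix.

    Index columns (``animal_id``, ``stage_hpf``) pass through untouched.
    Returns the scaled matrix and the fitted scaler (for the inverse
    transform).
    """
    meta_cols = [c for c in ("animal_id", "stage_hpf") if c in matrix.columns]
    data = matrix.drop(columns=meta_cols)
    scaler = FeatureScaler().fit(data)
    scaled = scaler.transform(data)
    return pd.concat([matrix[meta_cols], scaled], axis=1), scaler


def split_features(matrix: pd.DataFrame):
    """Split a feature matrix into (X DataFrame, stages, animals)."""
    meta_cols = [c for c in ("animal_id", "stage_hpf") if c in matrix.columns]
    X = matrix.drop(columns=meta_cols)
    y = matrix["stage_hpf"].to_numpy() if "stage_hpf" in matrix else None
    groups = matrix["animal_id"].to_numpy() if "animal_id" in matrix else None
    return X, y, groups
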