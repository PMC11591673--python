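"""Band registry: cluster fitted components into canonical bands, compute
per-(organ, stage) presence fractions, apply the >60% retention rule and
annotate retained bands with literature vibration assignments.

Across thousands of fitted spectra the same molecular vibration appears as a
cloud of component frequencies jittered by noise and fitting variance.
Components are grouped by single-linkage clustering on frequency: sort all
fitted F values and cut wherever the gap between consecutive values exceeds
``delta`` (default 10 cm^-1 — the closest distinct canonical bands, 1584 and
1603 cm^-1, are 19 cm^-1 apart, so this separates all of them while
absorbing fit jitter).  Each cluster becomes one canonical band labelled by
the rounded median frequency, e.g. "1409"; descriptor names like A1409 stay
stable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin


@dataclass
class BandCluster:
    """One canonical band grouping fitted components across spectra."""

    label: str
    canonical_F: float
    members: list[int] = field(default_factory=list)  # row indices into the component table


class BandClusterer(ClusterMixin, BaseEstimator):
    """Single-linkage 1-D clustering of band frequencies by gap cutting.

    Parameters
    ----------
    delta : float
        Gap threshold in cm^-1: consecutive sorted frequencies further apart
        than ``delta`` start a new cluster.

    Attributes
    ----------
    labels_ : ndarray of int
        Cluster index per input frequency (order-preserving).
    cluster_centers_ : ndarray
        Median frequency of each cluster, sorted ascending.
    band_labels_ : list of str
        Rounded-integer text label per cluster.
    """

    def __init__(self, delta: float = 10.0):
        self.delta = delta

    def fit(self, X, y=None):
        F = np.asarray(X, dtype=float).ravel()
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if F.size == 0:
            self.labels_ = np.empty(0, dtype=int)
            self.cluster_centers_ = np.empty(0)
            self.band_labels_ = []
            return self
        order = np.argsort(F, kind="stable")
        Fs = F[order]
        cuts = np.flatnonzero(np.diff(Fs) > self.delta)
        cluster_of_sorted = np.zeros(F.size, dtype=int)
        for c in cuts:
            cluster_of_sorted[c + 1 :] += 1
        labels = np.empty(F.size, dtype=int)
        labels[order] = cluster_of_sorted
        n = cluster_of_sorted[-1] + 1
        centers = np.array([np.median(Fs[cluster_of_sorted == k]) for k in range(n)])
        self.labels_ = labels
        self.cluster_centers_ = centers
        self.band_labels_ = _unique_labels(centers)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def _unique_labels(centers: np.ndarray) -> list[str]:
    labels = [str(int(round(c))) for c in centers]
    seen: dict[str, int] = {}
    out = []
    for lab in labels:
        if lab in seen:  # only possible for delta < 1 cm^-1
            seen[lab] += 1
            out.append(f"{lab}.{seen[lab]}")
        else:
            seen[lab] = 0
            out.append(lab)
    return out


def cluster_band_frequencies(
    components: pd.DataFrame, delta: float = 10.0
) -> tuple[list[BandCluster], pd.DataFrame]:
    """Group the fitted-component table into canonical bands.

    ``components`` must have an ``F`` column (rows with NaN F — fit reports
    of empty spectra — are ignored).  Returns the registry and a copy of the
    table with a ``band`` label column.
    """
    df = components.copy()
    valid = df["F"].notna()
    registry: list[BandCluster] = []
    df["band"] = pd.Series([None] * len(df), dtype=object)
    if valid.any():
        clus = BandClusterer(delta=delta).fit(df.loc[valid, "F"].to_numpy())
        lab_per_row = [clus.band_labels_[k] for k in clus.labels_]
        df.loc[valid, "band"] = lab_per_row
        idx = df.index[valid].to_numpy()
        for k, (center, lab) in enumerate(zip(clus.cluster_centers_, clus.band_labels_)):
            registry.append(
                BandCluster(
                    label=lab,
                    canonical_F=float(center),
                    members=list(idx[clus.labels_ == k]),
                )
            )
    return registry, df


def registry_frame(registry: list[BandCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"band": b.label, "canonical_F": b.canonical_F, "n_members": len(b.members)}
            for b in registry
        ],
        columns=["band", "canonical_F", "n_members"],
    )


def presence_table(
    labelled_components: pd.DataFrame, manifest: pd.DataFrame
) -> pd.DataFrame:
    """Fraction of animals presenting each band, per (organ, stage).

    An animal presents a band if any of its replicate spectra for that organ
    and stage contains a member component; replicate multiplicity never
    inflates the count.  The denominator is the number of animals measured
    for that (organ, stage) per the manifest; combinations with zero animals
    are omitted.  Long format: organ, stage_hpf, band, fraction, n_animals.
    """
    denom = (
        manifest.groupby(["organ", "stage_hpf"])["animal_id"]
        .nunique()
        .rename("n_animals")
        .reset_index()
    )
    comp = labelled_components.dropna(subset=["band"])
    present = (
        comp.groupby(["organ", "stage_hpf", "band"])["animal_id"]
        .nunique()
        .rename("n_present")
        .reset_index()
    )
    bands = sorted(comp["band"].unique())
    full = denom.merge(pd.DataFrame({"band": bands}), how="cross")
    out = full.merge(present, on=["organ", "stage_hpf", "band"], how="left")
    out["n_present"] = out["n_present"].fillna(0).astype(int)
    out["fraction"] = out["n_present"] / out["n_animals"]
    return out[["organ", "stage_hpf", "band", "fraction", "n_present", "n_animals"]]


def retain_bands(
    presence: pd.DataFrame, threshold: float = 0.60, window_size: int = 1
) -> dict[str, list[str]]:
    """Bands retained per organ under the strict >threshold presence rule.

    A band is retained for an organ iff there exists at least one time
    window (default: a single sampling stage) in which strictly more than
    ``threshold`` of the animals measured present the band.  A fraction of
    exactly ``threshold`` does not retain.  ``window_size > 1`` pools
    consecutive stages (animals present anywhere in the window count once).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    out: dict[str, list[str]] = {}
    for organ, sub in presence.groupby("organ"):
        stages = sorted(sub["stage_hpf"].unique())
        kept = set()
        for band, bs in sub.groupby("band"):
            bs = bs.set_index("stage_hpf")
            for i in range(len(stages) - window_size + 1):
                win = stages[i : i + window_size]
                rows = bs.loc[bs.index.isin(win)]
                if rows.empty:
                    continue
                # upper bound on animals present anywhere in the window
                n_pres = min(int(rows["n_present"].sum()), int(rows["n_animals"].max()))
                frac = (
                    float(rows["fraction"].iloc[0])
                    if window_size == 1
                    else n_pres / float(rows["n_animals"].max())
                )
                if frac > threshold:
                    kept.add(band)
                    break
        out[str(organ)] = sorted(kept, key=lambda s: float(s.split(".")[0]))
    return out


def retained_frame(retained: dict[str, list[str]]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"organ": o, "band": b} for o in sorted(retained) for b in retained[o]],
        columns=["organ", "band"],
    )


#: Literature molecular-vibration assignments for the 24 canonical bands.
BAND_ASSIGNMENTS: dict[str, tuple[str, str]] = {
    "223": ("unassigned", "-"),
    "621": ("unassigned", "-"),
    "796": ("O-P-O stretching / DNA phosphodiester", "zebrafish larvae literature"),
    "845": ("unassigned", "-"),
    "980": ("symmetric stretching of phosphate (PO4 3-)", "developing bone literature"),
    "1002": ("phenylalanine", "zebrafish organ literature"),
    "1032": ("aromatic amino acids (Phe/Trp/Tyr) / amide", "zebrafish brain literature"),
    "1156": ("aromatic amino acids / carotenoid-rich region", "zebrafish vasculature literature"),
    "1199": ("amide III", "zebrafish literature"),
    "1307": ("CH bending/scissoring", "zebrafish eye & heart literature"),
    "1375": ("CH bending/scissoring", "zebrafish eye & heart literature"),
    "1409": ("CH bending/scissoring", "zebrafish eye & heart literature"),
    "1450": ("CH bending/scissoring", "zebrafish eye & heart literature"),
    "1519": ("carotenoids / amide", "zebrafish yolk-sac literature"),
    "1584": ("unassigned", "-"),
    "1603": ("aromatic amino acids (Phe/Trp/Tyr) / amide I", "zebrafish organ literature"),
    "1639": ("amide I / C=C stretching", "zebrafish brain & liver literature"),
    "2852": ("CH stretching (lipids/proteins)", "zebrafish heart & liver literature"),
    "2929": ("CH stretching (CH2/CH3, lipids/proteins)", "zebrafish organ literature"),
    "2978": ("CH stretching (lipids/proteins)", "zebrafish literature"),
    "3002": ("CH stretching (lipids/proteins)", "zebrafish literature"),
    "3058": ("CH stretching", "zebrafish literature"),
    "3213": ("O-H stretching (water)", "zebrafish liver literature"),
    "3431": ("O-H stretching (water)", "zebrafish liver literature"),
}


@dataclass(frozen=True)
class BandAnnotation:
    band_label: str
    assignment: str
    source: str


def annotate_bands(labels) -> list[BandAnnotation]:
    """Literature vibration assignment per band label.

    Labels outside the 24 canonical bands are annotated "no literature assignment".
    """
    out = []
    for lab in labels:
        lab = str(lab)
        if lab in BAND_ASSIGNMENTS:
            assignment, source = BAND_ASSIGNMENTS[lab]
        else:
            assignment, source = "no literature assignment", "-"
        out.append(BandAnnotation(band_label=lab, assignment=assignment, source=source))
    return out


def annotation_frame(labels) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"band": a.band_label, "assignment": a.assignment, "source": a.source}
            for a in annotate_bands(labels)
        ],
        columns=["band", "assignment", "source"],
    )
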