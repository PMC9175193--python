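"""Feature engineering: tract profiles -> model-ready feature tables.

Two imaging representations are supported: the 40 histogram features
(mean M, standard deviation STD, skewness SK and excess kurtosis KU for
each of 5 metrics x 2 hemispheres, hemispheres relabelled ipsi/contra per
patient) and the raw 1000-dimensional segment vector (5 metrics x 2
hemispheres x 100 segments).  Clinical variables can be appended as an
extra block.  Imputation, standardisation and PCA always derive their
statistics from the training rows only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from cstmotor.config import METRICS, N_SEGMENTS

HIST_STATS = ("M", "STD", "SK", "KU")
SIDES = ("ipsi", "contra")


class FeatureError(ValueError):
    """Raised on invalid feature-engineering inputs."""


def histogram_features(values: np.ndarray) -> dict[str, float]:
    """M/STD/SK/KU of one profile, ignoring missing segments.

    M is the arithmetic mean; STD the sample standard deviation (n-1);
    SK the moment skewness g1 = m3 / m2^1.5 and KU the excess kurtosis
    g2 = m4 / m2^2 - 3 (population central moments).  A zero-variance
    profile yields SK = KU = 0 by convention.  Requires at least 4 valid
    segments.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[~np.isnan(v)]
    if v.size < 4:
        raise FeatureError(f"need >= 4 valid segments, got {v.size}")
    m = float(v.mean())
    std = float(v.std(ddof=1))
    d = v - m
    m2 = float(np.mean(d ** 2))
    if m2 == 0.0:
        return {"M": m, "STD": 0.0, "SK": 0.0, "KU": 0.0}
    m3 = float(np.mean(d ** 3))
    m4 = float(np.mean(d ** 4))
    return {"M": m, "STD": std, "SK": m3 / m2 ** 1.5, "KU": m4 / m2 ** 2 - 3.0}


@dataclass
class FeatureTable:
    """Patients x features matrix with class labels and column metadata."""

    X: pd.DataFrame
    y: pd.Series
    imaging_columns: list[str] = dc_field(default_factory=list)
    clinical_columns: list[str] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise FeatureError("labels must match rows")
        if self.X.columns.duplicated().any():
            raise FeatureError("feature names must be unique")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def subset(self, index) -> "FeatureTable":
        return FeatureTable(self.X.iloc[index].reset_index(drop=True),
                            self.y.iloc[index].reset_index(drop=True),
                            list(self.imaging_columns), list(self.clinical_columns))

    def with_X(self, X: pd.DataFrame) -> "FeatureTable":
        imaging = [c for c in X.columns if c in set(self.imaging_columns)]
        clinical = [c for c in X.columns if c in set(self.clinical_columns)]
        return FeatureTable(X, self.y.reset_index(drop=True), imaging, clinical)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = self.X.copy()
        df.insert(0, "label", self.y.to_numpy())
        df.to_csv(path, index=False)
        meta = {"imaging_columns": self.imaging_columns,
                "clinical_columns": self.clinical_columns}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        y = df.pop("label")
        return cls(df, y, meta.get("imaging_columns", list(df.columns)),
                   meta.get("clinical_columns", []))


def _clinical_block(patients) -> pd.DataFrame:
    rows = []
    for p in patients:
        row = {
            "age": p.age,
            "gender_male": 1.0 if p.gender == "male" else 0.0,
            "who_grade": {"II": 2.0, "III": 3.0, "IV": 4.0}[p.who_grade],
            "rmt_ipsi": p.rmt_ipsi,
            "rmt_contra": p.rmt_contra,
        }
        for loc in ("frontal", "parietal", "insular", "temporal"):
            row[f"loc_{loc}"] = 1.0 if p.tumour_location == loc else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def assemble_features(profiles: dict, patients, mode: str = "histogram40",
                      clinical: bool = False,
                      metrics: tuple[str, ...] = METRICS) -> FeatureTable:
    """Build a FeatureTable from per-patient profiles.

    Parameters
    ----------
    profiles
        Mapping ``(patient_id, hemisphere, metric) -> (100,)`` profile array
        (NaN = missing segment).  Hemispheres are anatomical (left/right)
        and are relabelled ipsi/contra using each patient's lesion side.
    mode
        ``histogram40`` (4 stats per metric/side), ``segments1000`` (raw
        segment values) or ``clinical`` (clinical block only).
    clinical
        Append the clinical/demographic block (age, gender, WHO grade,
        one-hot tumour location, ipsi/contra RMT) to an imaging mode.
    """
    if mode not in ("histogram40", "segments1000", "clinical"):
        raise FeatureError(f"unknown feature mode {mode!r}")
    labels = pd.Series([p.mrc_class for p in patients], name="label")

    imaging = pd.DataFrame(index=range(len(patients)))
    imaging_cols: list[str] = []
    if mode != "clinical":
        rows = []
        for p in patients:
            sides = {"ipsi": p.ipsilesional_hemisphere,
                     "contra": p.contralesional_hemisphere}
            row = {}
            for metric in metrics:
                for side, hemi in sides.items():
                    key = (p.id, hemi, metric)
                    if key not in profiles:
                        raise FeatureError(
                            f"missing profile for patient {p.id}, metric {metric}, "
                            f"hemisphere {hemi}")
                    prof = np.asarray(profiles[key], dtype=float)
                    if mode == "histogram40":
                        stats = histogram_features(prof)
                        for stat in HIST_STATS:
                            row[f"{metric}_{stat}_{side}"] = stats[stat]
                    else:
                        for j in range(N_SEGMENTS):
                            row[f"{metric}_{side}_s{j:02d}"] = prof[j]
            rows.append(row)
        imaging = pd.DataFrame(rows)
        imaging_cols = list(imaging.columns)

    clinical_cols: list[str] = []
    if clinical or mode == "clinical":
        block = _clinical_block(patients)
        clinical_cols = list(block.columns)
        imaging = pd.concat([imaging, block], axis=1) if imaging_cols else block

    return FeatureTable(imaging, labels, imaging_cols, clinical_cols)


# ---------------------------------------------------------------------------
# Train-only transforms


def impute_missing(train: pd.DataFrame, test: pd.DataFrame | None = None,
                   method: str = "median", k: int = 10):
    """Fill missing cells using statistics of the training rows only.

    ``median``: train column medians fill both sets.  ``knn``: each
    incomplete row is filled from its ``k`` nearest training rows, by
    Euclidean distance over the columns observed in both rows; the fill
    value is the mean of the neighbours' observed values in that column
    (falling back to the train column median when no neighbour observes
    it).  Ties in distance are broken by training-row order.
    """
    if method not in ("median", "knn"):
        raise FeatureError(f"unknown imputation method {method!r}")
    if len(train) == 0:
        raise FeatureError("training table is empty")
    Xtr = train.to_numpy(dtype=float)
    with warnings.catch_warnings():
        # all-NaN columns are reported as a FeatureError just below
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_medians = np.nanmedian(Xtr, axis=0)
    if np.any(np.isnan(col_medians)):
        bad = train.columns[np.isnan(col_medians)].tolist()
        raise FeatureError(f"columns entirely missing in train: {bad}")

    def _fill_median(df: pd.DataFrame) -> pd.DataFrame:
        X = df.to_numpy(dtype=float).copy()
        ii, jj = np.where(np.isnan(X))
        X[ii, jj] = col_medians[jj]
        return pd.DataFrame(X, columns=df.columns)

    if method == "median":
        out_tr = _fill_median(train)
        out_te = _fill_median(test) if test is not None else None
        return (out_tr, out_te) if test is not None else out_tr

    # pairwise squared distances over mutually observed columns, computed
    # with zero-filled matrices and observation masks
    Tz = np.nan_to_num(Xtr)
    Tm = (~np.isnan(Xtr)).astype(float)

    def _fill_knn(df: pd.DataFrame, is_train: bool) -> pd.DataFrame:
        X = df.to_numpy(dtype=float).copy()
        Qz = np.nan_to_num(X)
        Qm = (~np.isnan(X)).astype(float)
        d2 = ((Qz ** 2) @ Tm.T) + (Qm @ (Tz ** 2).T) - 2.0 * (Qz @ Tz.T)
        n_mutual = Qm @ Tm.T
        d2 = np.where(n_mutual > 0, np.maximum(d2, 0.0), np.inf)
        if is_train:
            np.fill_diagonal(d2, np.inf)
        for i in range(X.shape[0]):
            miss = np.isnan(X[i])
            if not miss.any():
                continue
            order = np.argsort(d2[i], kind="stable")   # ties -> row order
            nn = order[np.isfinite(d2[i][order])][:k]
            for j in np.where(miss)[0]:
                vals = Xtr[nn, j]
                vals = vals[~np.isnan(vals)]
                X[i, j] = vals.mean() if vals.size else col_medians[j]
        return pd.DataFrame(X, columns=df.columns)

    out_tr = _fill_knn(train, is_train=True)
    out_te = _fill_knn(test, is_train=False) if test is not None else None
    return (out_tr, out_te) if test is not None else out_tr


@dataclass
class StandardizeParams:
    mean: np.ndarray
    scale: np.ndarray
    columns: list[str]

    def inverse(self, df: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(df.to_numpy() * self.scale + self.mean,
                            columns=df.columns)


def standardize(train: pd.DataFrame, test: pd.DataFrame | None = None):
    """z-score both sets with train mean/SD; zero-variance columns get
    scale 1 (centred but not scaled).  Returns (train, test, params)."""
    mean = train.to_numpy(dtype=float).mean(axis=0)
    sd = train.to_numpy(dtype=float).std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    params = StandardizeParams(mean, scale, list(train.columns))

    def _tx(df):
        return pd.DataFrame((df.to_numpy(dtype=float) - mean) / scale,
                            columns=df.columns)

    out_te = _tx(test) if test is not None else None
    return _tx(train), out_te, params


def pca_reduce(train: pd.DataFrame, test: pd.DataFrame | None = None,
               n_components: int = 4):
    """Project both sets on the first ``n_components`` principal components
    fitted on the (already standardised) training rows."""
    max_nc = min(len(train) - 1, train.shape[1])
    if n_components > max_nc:
        raise FeatureError(
            f"n_components={n_components} exceeds min(rows-1, columns)={max_nc}")
    pca = PCA(n_components=n_components, svd_solver="full")
    tr = pca.fit_transform(train.to_numpy(dtype=float))
    cols = [f"PC{i + 1}" for i in range(n_components)]
    out_tr = pd.DataFrame(tr, columns=cols)
    out_te = None
    if test is not None:
        out_te = pd.DataFrame(pca.transform(test.to_numpy(dtype=float)), columns=cols)
    return out_tr, out_te, pca
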