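"""Peak-intensity tables and the preprocessing steps applied before modelling.

A :class:`PeakTable` holds a samples x features matrix of non-negative LC-MS
peak areas together with per-feature retention time / m/z annotations and an
optional binary syndrome label per sample (1 = excess, the minority class;
0 = deficiency).  Preprocessing follows the acquisition protocol's order:
internal-standard removal first, then total-intensity (sum) normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "remove_internal_standard",
    "sum_normalize",
    "autoscale",
    "assemble_matrix",
    "read_peak_table",
    "write_peak_table",
]


@dataclass
class PeakTable:
    """Samples x features positive-intensity matrix with feature metadata.

    Parameters
    ----------
    intensities : ndarray, shape (n_samples, n_features)
        Non-negative peak areas.
    feature_ids : sequence of str
    rt : ndarray
        Retention times in minutes, one per feature.
    mz : ndarray
        Mass-to-charge ratios, one per feature.
    sample_ids : sequence of str
        Unique sample identifiers.
    labels : ndarray or None
        Binary syndrome labels (1 = excess, 0 = deficiency), one per sample.
    """

    intensities: np.ndarray
    feature_ids: list = field(default_factory=list)
    rt: np.ndarray = None
    mz: np.ndarray = None
    sample_ids: list = field(default_factory=list)
    labels: np.ndarray = None

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D samples x features matrix")
        n_samples, n_features = self.intensities.shape
        if np.any(self.intensities < 0):
            raise ValueError("negative intensities are not allowed")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("missing or non-finite intensities are not supported")
        self.feature_ids = [str(f) for f in self.feature_ids]
        if len(self.feature_ids) != n_features:
            raise ValueError(
                f"feature_ids length {len(self.feature_ids)} != feature count {n_features}"
            )
        self.rt = np.asarray(self.rt, dtype=float)
        self.mz = np.asarray(self.mz, dtype=float)
        if self.rt.shape != (n_features,) or self.mz.shape != (n_features,):
            raise ValueError("rt and mz must have one entry per feature")
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.sample_ids) != n_samples:
            raise ValueError("sample_ids length must equal the sample count")
        if len(set(self.sample_ids)) != n_samples:
            raise ValueError("sample ids must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n_samples,):
                raise ValueError("labels must have one entry per sample")
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be binary (0 = deficiency, 1 = excess)")

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    def select_features(self, index) -> "PeakTable":
        """Return a copy restricted to the given feature index (bool or int)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(
            self,
            intensities=self.intensities[:, index].copy(),
            feature_ids=[self.feature_ids[i] for i in index],
            rt=self.rt[index].copy(),
            mz=self.mz[index].copy(),
        )


def remove_internal_standard(
    table: PeakTable,
    is_mz: float,
    is_rt: float,
    mz_tol: float = 0.01,
    rt_tol: float = 0.1,
) -> PeakTable:
    """Drop all features matching the internal standard's (m/z, rt) window.

    A feature matches when ``|mz - is_mz| <= mz_tol`` and
    ``|rt - is_rt| <= rt_tol``.  Removal happens before sum-normalization so
    the spiked reference compound does not distort per-sample totals.
    """
    if mz_tol <= 0 or rt_tol <= 0:
        raise ValueError("tolerances must be positive")
    match = (np.abs(table.mz - is_mz) <= mz_tol) & (np.abs(table.rt - is_rt) <= rt_tol)
    n_removed = int(match.sum())
    if n_removed == table.n_features:
        raise ValueError("internal-standard removal would leave zero features")
    if n_removed == 0:
        logger.warning(
            "no feature within mz %.4f±%.4f / rt %.2f±%.2f; table unchanged",
            is_mz, mz_tol, is_rt, rt_tol,
        )
        return table
    logger.info("removed %d internal-standard feature(s)", n_removed)
    return table.select_features(~match)


def sum_normalize(table: PeakTable) -> PeakTable:
    """Divide each sample's intensities by its total so each row sums to 1."""
    totals = table.intensities.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        raise ValueError(
            f"sample(s) with zero total intensity: {[table.sample_ids[i] for i in bad]}"
        )
    return replace(table, intensities=table.intensities / totals[:, None])


def autoscale(X: np.ndarray) -> np.ndarray:
    """Unit-variance (auto) scaling: center each column and divide by its SD.

    Normalized peak areas span orders of magnitude across metabolites, so a
    Euclidean-distance kernel on raw columns is dominated by the most abundant
    features and is nearly blind to fold-changes on low-abundance ones.
    Autoscaling — the conventional chemometrics remedy — gives every feature
    equal a-priori weight.  Constant columns are centered only.
    """
    X = np.asarray(X, dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - X.mean(axis=0)) / sd


def assemble_matrix(table: PeakTable):
    """Extract the modelling matrix ``(X, y)`` with a stable column order.

    Returns
    -------
    X : ndarray, shape (n_samples, n_features)
    y : ndarray of {0, 1}
        1 = excess (minority class).
    feature_ids : list of str
        The column order of X.
    """
    if table.n_samples == 0 or table.n_features == 0:
        raise ValueError("empty peak table")
    if table.labels is None:
        raise ValueError("labels are required to assemble the modelling matrix")
    return table.intensities.copy(), table.labels.copy(), list(table.feature_ids)


def write_peak_table(table: PeakTable, path, labels_path=None, sep="\t") -> None:
    """Write a features-as-rows table: feature_id, rt_min, mz, one column per sample.

    If ``labels_path`` is given and the table carries labels, a two-column
    ``sample_id<sep>label`` file is written alongside.
    """
    df = pd.DataFrame(
        {"feature_id": table.feature_ids, "rt_min": table.rt, "mz": table.mz}
    )
    for i, sid in enumerate(table.sample_ids):
        df[sid] = table.intensities[i, :]
    df.to_csv(path, sep=sep, index=False)
    if labels_path is not None:
        if table.labels is None:
            raise ValueError("table has no labels to write")
        pd.DataFrame({"sample_id": table.sample_ids, "label": table.labels}).to_csv(
            labels_path, sep=sep, index=False
        )


def read_peak_table(path, labels_path=None, sep="\t") -> PeakTable:
    """Read the dialect written by :func:`write_peak_table`."""
    df = pd.read_csv(path, sep=sep)
    required = ["feature_id", "rt_min", "mz"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"first three columns must be {required}")
    sample_ids = list(df.columns[3:])
    labels = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path, sep=sep)
        lab = lab.set_index("sample_id")["label"]
        missing = [s for s in sample_ids if s not in lab.index]
        if missing:
            raise ValueError(f"missing label for sample(s): {missing}")
        labels = lab.loc[sample_ids].to_numpy()
    return PeakTable(
        intensities=df[sample_ids].to_numpy(dtype=float).T,
        feature_ids=df["feature_id"].astype(str).tolist(),
        rt=df["rt_min"].to_numpy(dtype=float),
        mz=df["mz"].to_numpy(dtype=float),
        sample_ids=sample_ids,
        labels=labels,
    )
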