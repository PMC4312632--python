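"""Synthetic imbalanced metabolomics cohorts with known ground truth.

The generator emulates the shape of a serum LC-MS peak-area export from an
imbalanced two-class diabetic cohort: a majority "deficiency" class (default
238 samples) and a minority "excess" class (default 57), ~135 annotated
features with log-normal positive intensities and multiplicative noise, an
internal-standard feature at fixed (rt, m/z), and a small set of planted
up-regulated features that stand in for real differential metabolites.
Effects are planted on the log scale so intensities stay strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import PeakTable

__all__ = ["SyntheticSpec", "GroundTruth", "generate_cohort", "generate_clinical_table",
           "IS_MZ", "IS_RT"]

# internal standard: L-chlorophenylalanine-like [M+H]+ coordinates
IS_MZ = 200.0473
IS_RT = 1.95


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic two-class cohort.

    Defaults mirror the study conditions: 238 majority (deficiency) vs 57
    minority (excess) samples, 135 features including one internal standard,
    and 4 informative up-regulated features.

    ``log2_effect`` is the per-informative-feature shift of the minority
    class in log2-intensity units (1.0 = two-fold).  ``cv_noise`` is the
    coefficient of variation of the multiplicative log-normal noise.
    """

    n_class0: int = 238
    n_class1: int = 57
    n_features: int = 135
    n_informative: int = 4
    log2_effect: float = 1.0
    cv_noise: float = 0.3
    include_internal_standard: bool = True
    seed: int = 0
    effect_directions: np.ndarray = None  # per-informative sign, default all +1

    def __post_init__(self):
        if self.n_class0 <= 0 or self.n_class1 <= 0 or self.n_features <= 0:
            raise ValueError("sample and feature counts must be positive")
        n_plain = self.n_features - int(self.include_internal_standard)
        if not 0 <= self.n_informative <= n_plain:
            raise ValueError("n_informative must be between 0 and the number of "
                             "non-internal-standard features")
        if not np.isfinite(self.log2_effect):
            raise ValueError("log2_effect must be finite")
        if self.cv_noise <= 0:
            raise ValueError("cv_noise must be positive")
        if self.effect_directions is not None:
            self.effect_directions = np.asarray(self.effect_directions, dtype=int)
            if self.effect_directions.shape != (self.n_informative,):
                raise ValueError("effect_directions must have length n_informative")
            if not np.isin(self.effect_directions, [-1, 1]).all():
                raise ValueError("effect directions must be +1 or -1")


@dataclass
class GroundTruth:
    """Which synthetic features carry a planted class effect, and its sign."""

    informative_feature_ids: list
    effect_direction: np.ndarray

    def __post_init__(self):
        self.effect_direction = np.asarray(self.effect_direction, dtype=int)
        if len(self.informative_feature_ids) != len(self.effect_direction):
            raise ValueError("ids and directions must have equal length")
        if not np.isin(self.effect_direction, [-1, 1]).all():
            raise ValueError("directions must be +1 or -1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"feature_id": self.informative_feature_ids,
             "direction": self.effect_direction}
        )


def generate_cohort(spec: SyntheticSpec):
    """Draw one synthetic cohort.

    Returns
    -------
    table : PeakTable
        Positive intensities, shape (n_class0 + n_class1, n_features);
        class-0 samples come first.  Labels are attached (1 = minority).
    labels : ndarray
    truth : GroundTruth

    Intensity model: per-feature baseline log-intensity drawn once from a
    wide normal (spanning ~2 orders of magnitude across features), plus i.i.d.
    normal noise on the log scale with SD matched to ``cv_noise``; minority
    samples of informative features get an additional ``log2_effect * log 2``
    shift in the planted direction.  Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_class0 + spec.n_class1
    labels = np.concatenate(
        [np.zeros(spec.n_class0, dtype=int), np.ones(spec.n_class1, dtype=int)]
    )

    n_plain = spec.n_features - int(spec.include_internal_standard)
    # feature annotations
    rt = rng.uniform(0.5, 9.5, size=n_plain)
    mz = rng.uniform(100.0, 1000.0, size=n_plain)
    base_log = rng.normal(np.log(1.0e4), 1.2, size=n_plain)

    sigma = np.sqrt(np.log1p(spec.cv_noise ** 2))
    log_x = base_log[None, :] + rng.normal(0.0, sigma, size=(n, n_plain))

    informative = np.sort(rng.choice(n_plain, size=spec.n_informative, replace=False))
    directions = (
        spec.effect_directions
        if spec.effect_directions is not None
        else np.ones(spec.n_informative, dtype=int)
    )
    shift = spec.log2_effect * np.log(2.0)
    for k, j in enumerate(informative):
        log_x[labels == 1, j] += directions[k] * shift

    intensities = np.exp(log_x)
    feature_ids = [f"M{j + 1:04d}" for j in range(n_plain)]

    if spec.include_internal_standard:
        # near-constant spiked reference compound, removed during preprocessing
        is_col = np.exp(rng.normal(np.log(5.0e4), 0.05, size=(n, 1)))
        intensities = np.hstack([intensities, is_col])
        feature_ids = feature_ids + ["IS"]
        rt = np.append(rt, IS_RT)
        mz = np.append(mz, IS_MZ)

    table = PeakTable(
        intensities=intensities,
        feature_ids=feature_ids,
        rt=rt,
        mz=mz,
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        labels=labels,
    )
    truth = GroundTruth(
        informative_feature_ids=[f"M{j + 1:04d}" for j in informative],
        effect_direction=directions,
    )
    return table, labels, truth


# default clinical covariates: (excess mean, excess sd, deficiency mean, deficiency sd)
DEFAULT_CONTINUOUS = {
    "age": (67.11, 9.49, 71.55, 8.50),
    "bmi": (24.57, 2.44, 25.46, 2.98),
    "sbp": (136.53, 14.40, 138.49, 14.73),
    "dbp": (79.72, 9.62, 78.10, 9.43),
}
# (excess proportion, deficiency proportion)
DEFAULT_BINARY = {
    "obesity": (0.456, 0.534),
    "fatty_liver": (0.667, 0.769),
    "hypertension": (0.877, 0.924),
}


def generate_clinical_table(
    n_subjects: int,
    group_labels,
    seed: int = 0,
    continuous: dict | None = None,
    binary: dict | None = None,
) -> pd.DataFrame:
    """Simulate a clinical covariate table for a labelled cohort.

    ``continuous`` maps column name -> (mean1, sd1, mean0, sd0) where group 1
    is the minority (excess) class; ``binary`` maps column name ->
    (proportion1, proportion0).  Defaults emulate typical elderly type-2
    diabetic cohort characteristics.
    """
    group_labels = np.asarray(group_labels, dtype=int)
    if group_labels.shape != (n_subjects,):
        raise ValueError("group_labels length must equal n_subjects")
    rng = np.random.default_rng(seed)
    continuous = DEFAULT_CONTINUOUS if continuous is None else continuous
    binary = DEFAULT_BINARY if binary is None else binary

    out = {"sample_id": [f"S{i + 1:04d}" for i in range(n_subjects)],
           "group": group_labels}
    is1 = group_labels == 1
    for name, (m1, s1, m0, s0) in continuous.items():
        col = np.where(
            is1,
            rng.normal(m1, s1, size=n_subjects),
            rng.normal(m0, s0, size=n_subjects),
        )
        out[name] = col
    for name, (p1, p0) in binary.items():
        p = np.where(is1, p1, p0)
        out[name] = (rng.random(n_subjects) < p).astype(int)
    return pd.DataFrame(out)
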