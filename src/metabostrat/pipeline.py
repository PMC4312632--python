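"""End-to-end stratification: preprocess -> SMOTE tuning -> GA-K-OPLS
selection -> final model tuning/evaluation -> differential calling.

The orchestration is exposed statsmodels-style: a :class:`SyndromeStratifier`
model is built from a labelled :class:`~metabostrat.peaks.PeakTable`, and
``fit()`` returns a :class:`StratificationResults` object carrying the model
report, the differential-metabolite calls, the selection tallies and a
``summary()`` table.  A master seed derives per-stage seeds so stages are
individually reproducible.

Final-model metrics are computed on the ORIGINAL (non-augmented) cohort —
reporting on SMOTE-augmented data would inflate sensitivity.  Because that
evaluation overlaps the training data (the protocol's own choice), an
honest strict-holdout report is produced alongside, clearly labelled.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .cohort import clinical_summary_table  # noqa: F401  (re-export convenience)
from .ga import GAConfig, SelectionCounts, repeat_runs
from .kopls import (
    DEFAULT_AO_GRID,
    DEFAULT_SIGMA_GRID,
    KOPLS,
    KoplsConfig,
    grid_search_accv,
)
from .metrics import ModelReport
from .peaks import (
    PeakTable,
    assemble_matrix,
    autoscale,
    remove_internal_standard,
    sum_normalize,
)
from .significance import call_differentials, wilcoxon_rank_sum
from .smote import SmoteConfig, optimize_smote_n, rebalance

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SyndromeStratifier", "StratificationResults", "run_full"]


@dataclass
class PipelineConfig:
    """All knobs of the stratification pipeline, with study-protocol defaults."""

    # preprocessing: internal-standard coordinates (None skips removal)
    is_mz: float | None = None
    is_rt: float | None = None
    mz_tol: float = 0.01
    rt_tol: float = 0.1
    # feature scaling before modelling: "uv" (unit variance) or "none".
    # Without it the kernel distance is dominated by high-abundance features.
    scale: str = "uv"
    # SMOTE: neighbor grid searched by the wrapper (None fixes smote.n_neighbors)
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    smote_n_grid: tuple | None = tuple(range(1, 11))
    smote_n_repeats: int = 10
    strict_holdout: bool = False
    # GA selection
    ga: GAConfig = field(default_factory=GAConfig)
    ga_kopls: KoplsConfig = field(default_factory=lambda: KoplsConfig(sigma="median", ao=1))
    # final model tuning
    sigma_grid: tuple = DEFAULT_SIGMA_GRID
    ao_grid: tuple = DEFAULT_AO_GRID
    n_folds: int = 10
    # significance thresholds
    alpha_ga: float = 0.001
    alpha_wx: float = 0.05
    compute_strict_report: bool = True
    seed: int = 0

    def to_json(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            if isinstance(o, np.ndarray):
                return o.tolist()
            return str(o)

        return json.dumps(self.__dict__, default=enc, sort_keys=True)


class SyndromeStratifier:
    """Two-class metabolomics stratification model.

    Parameters
    ----------
    table : PeakTable
        Raw (unnormalized) peak areas with binary labels attached
        (1 = excess / minority, 0 = deficiency / majority).
    config : PipelineConfig, optional

    Examples
    --------
    >>> spec = SyntheticSpec(seed=7)
    >>> table, y, truth = generate_cohort(spec)
    >>> model = SyndromeStratifier(table, config)
    >>> res = model.fit()
    >>> print(res.summary())
    """

    def __init__(self, table: PeakTable, config: PipelineConfig | None = None):
        if table.labels is None:
            raise ValueError("the peak table must carry binary labels")
        self.table = table
        self.config = config if config is not None else PipelineConfig()

    @classmethod
    def from_files(cls, peak_path, labels_path, config=None, sep="\t"):
        from .peaks import read_peak_table

        return cls(read_peak_table(peak_path, labels_path, sep=sep), config)

    # ------------------------------------------------------------------
    def _preprocess(self):
        cfg = self.config
        table = self.table
        if cfg.is_mz is not None and cfg.is_rt is not None:
            table = remove_internal_standard(
                table, cfg.is_mz, cfg.is_rt, cfg.mz_tol, cfg.rt_tol
            )
        table = sum_normalize(table)
        X, y, feature_ids = assemble_matrix(table)
        if cfg.scale not in ("uv", "none"):
            raise ValueError("scale must be 'uv' or 'none'")
        if cfg.scale == "uv":
            X = autoscale(X)
        return X, y, feature_ids

    def fit(self) -> "StratificationResults":
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed)
        seed_smote, seed_ga, seed_final, seed_strict = [
            int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)
        ]

        logger.info("stage 1/5: preprocessing")
        X, y, feature_ids = self._preprocess()

        logger.info("stage 2/5: SMOTE neighbor-parameter optimization")
        if cfg.smote_n_grid:
            best_n, smote_table = optimize_smote_n(
                X, y, cfg.smote_n_grid, cfg.ga, cfg.ga_kopls,
                n_repeats=cfg.smote_n_repeats, seed=seed_smote,
                target_ratio=cfg.smote.target_ratio,
                strict_holdout=cfg.strict_holdout,
            )
        else:
            best_n, smote_table = cfg.smote.n_neighbors, None
        smote_cfg = SmoteConfig(
            n_neighbors=best_n, target_ratio=cfg.smote.target_ratio
        )

        logger.info("stage 3/5: %d GA-K-OPLS selection runs", cfg.ga.n_runs)
        counts = repeat_runs(
            X, y, cfg.ga, smote_cfg, cfg.ga_kopls,
            seed=seed_ga, strict_holdout=cfg.strict_holdout,
        )

        logger.info("stage 4/5: differential calling")
        calls = call_differentials(
            counts, X, y, feature_ids, alpha_ga=cfg.alpha_ga, alpha_wx=cfg.alpha_wx
        )
        selected = calls["p_ga"] < cfg.alpha_ga
        if not selected.any():
            # no feature clears the frequency threshold: fall back to the m
            # most-selected features so a final model can still be reported
            order = np.argsort(-counts.counts, kind="stable")
            selected = np.zeros(counts.v, dtype=bool)
            selected[order[: counts.m]] = True
            logger.warning(
                "no feature passed the selection-frequency threshold; "
                "using the %d most-selected features for the final model",
                counts.m,
            )
        selected = np.asarray(selected, dtype=bool)
        sel_ids = [feature_ids[j] for j in np.flatnonzero(selected)]
        X_sel = X[:, selected]

        logger.info("stage 5/5: final K-OPLS tuning and evaluation")
        rng_final = np.random.default_rng(seed_final)
        X_aug, y_aug = rebalance(X_sel, y, smote_cfg, rng=rng_final)
        surface, best_sigma, best_ao = grid_search_accv(
            X_aug, y_aug, cfg.sigma_grid, cfg.ao_grid,
            n_folds=cfg.n_folds, seed=seed_final,
        )
        kres = KOPLS(X_aug, y_aug, sigma=best_sigma, n_ortho=best_ao).fit()
        report = kres.evaluate(X_sel, y, n_folds=cfg.n_folds, seed=seed_final)

        report_strict = None
        if cfg.compute_strict_report:
            report_strict = self._strict_report(
                X_sel, y, smote_cfg, best_sigma, best_ao, seed_strict
            )

        return StratificationResults(
            model=self,
            X=X, y=y, feature_ids=feature_ids,
            best_smote_n=best_n, smote_error_table=smote_table,
            selection_counts=counts, calls=calls,
            selected_features=sel_ids, selected_mask=selected,
            accv_surface=surface, report=report, report_strict=report_strict,
            kopls_results=kres,
        )

    def _strict_report(self, X_sel, y, smote_cfg, sigma, ao, seed):
        """Held-out evaluation: tune nothing on the test half."""
        tr, te = train_test_split(
            np.arange(y.size), test_size=0.5, stratify=y, random_state=seed % (2 ** 31)
        )
        rng = np.random.default_rng(seed)
        X_aug, y_aug = rebalance(X_sel[tr], y[tr], smote_cfg, rng=rng)
        n_folds = min(self.config.n_folds, int(np.bincount(y_aug).min()))
        kres = KOPLS(X_aug, y_aug, sigma=sigma, n_ortho=ao).fit()
        return kres.evaluate(X_sel[te], y[te], n_folds=n_folds, seed=seed)


@dataclass
class StratificationResults:
    """Everything the fitted pipeline produced."""

    model: SyndromeStratifier
    X: np.ndarray
    y: np.ndarray
    feature_ids: list
    best_smote_n: int
    smote_error_table: pd.DataFrame | None
    selection_counts: SelectionCounts
    calls: pd.DataFrame
    selected_features: list
    selected_mask: np.ndarray
    accv_surface: pd.DataFrame
    report: ModelReport
    report_strict: ModelReport | None
    kopls_results: object

    @property
    def called(self) -> pd.DataFrame:
        """The differential calls passing the dual criterion."""
        return self.calls[self.calls["passes"]].reset_index(drop=True)

    def summary(self) -> str:
        r = self.report
        lines = [
            "Metabolomics stratification results",
            "=" * 40,
            f"samples: {self.y.size} ({int(self.y.sum())} excess / "
            f"{int((1 - self.y).sum())} deficiency), features: {len(self.feature_ids)}",
            f"SMOTE neighbor parameter n: {self.best_smote_n}",
            f"GA runs: {self.selection_counts.n}, mean selected per run (m): "
            f"{self.selection_counts.m}",
            f"features in final model: {len(self.selected_features)}",
            "",
            "Final K-OPLS model (evaluated on the original cohort)",
            f"  sigma={r.sigma:.4g}  Ao={r.ao}  ACCV={r.accv:.3f}",
            f"  R2X={r.r2x:.3f}  R2Y={r.r2y:.3f}  Q2Y={r.q2y:.3f}",
            f"  AUC={r.auc:.3f} (95% CI {r.auc_ci_low:.3f}-{r.auc_ci_high:.3f})",
            f"  sensitivity={r.sensitivity:.3f}  specificity={r.specificity:.3f}",
            f"  total accuracy={r.total_accuracy:.3f}  "
            f"balanced accuracy={r.balanced_accuracy:.3f}",
        ]
        if self.report_strict is not None:
            s = self.report_strict
            lines += [
                "Strict held-out evaluation",
                f"  AUC={s.auc:.3f}  sensitivity={s.sensitivity:.3f}  "
                f"specificity={s.specificity:.3f}  balanced accuracy="
                f"{s.balanced_accuracy:.3f}",
            ]
        called = self.called
        lines.append("")
        lines.append(f"differential metabolites called: {len(called)}")
        for _, row in called.iterrows():
            arrow = "up in excess" if row.direction > 0 else "down in excess"
            lines.append(
                f"  {row.feature_id}: selected {row.x}/{row.n} runs, "
                f"P_GA={row.p_ga:.2e}, P_Wilcoxon={row.p_wilcoxon:.2e} ({arrow})"
            )
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def subgroup_robustness(self, covariate, cutoff: float):
        """Re-analysis within covariate-defined subgroups.

        Splits samples into low (<= cutoff) and high (> cutoff), refits the
        final K-OPLS model (same sigma, Ao, selected features) within each
        nonempty subgroup, and tests each called feature between the two
        subgroups with the Mann-Whitney test.

        Returns a dict with per-subgroup :class:`ModelReport` (or None for an
        empty subgroup), subgroup sizes, and a DataFrame of between-subgroup
        P values for the called features.
        """
        covariate = np.asarray(covariate, dtype=float)
        if covariate.shape != self.y.shape:
            raise ValueError("covariate must have one value per sample")
        low = covariate <= cutoff
        high = ~low
        cfg = self.model.config
        r = self.report
        smote_cfg = SmoteConfig(
            n_neighbors=self.best_smote_n, target_ratio=cfg.smote.target_ratio
        )
        X_sel = self.X[:, self.selected_mask]

        reports, sizes = {}, {}
        for name, idx in (("low", low), ("high", high)):
            sizes[name] = int(idx.sum())
            if sizes[name] == 0:
                reports[name] = None
                continue
            ys = self.y[idx]
            if len(np.unique(ys)) < 2:
                raise ValueError(f"subgroup '{name}' lacks one of the classes")
            rng = np.random.default_rng(cfg.seed)
            X_aug, y_aug = rebalance(X_sel[idx], ys, smote_cfg, rng=rng)
            n_folds = min(cfg.n_folds, int(np.bincount(y_aug).min()))
            kres = KOPLS(X_aug, y_aug, sigma=r.sigma, n_ortho=r.ao).fit()
            reports[name] = kres.evaluate(
                X_sel[idx], ys, n_folds=n_folds, seed=cfg.seed
            )

        rows = []
        for fid in self.called["feature_id"]:
            j = self.feature_ids.index(fid)
            if low.any() and high.any():
                p = wilcoxon_rank_sum(self.X[high, j], self.X[low, j])
            else:
                p = float("nan")
            rows.append({"feature_id": fid, "p_between_subgroups": p})
        return {
            "reports": reports,
            "sizes": sizes,
            "feature_tests": pd.DataFrame(rows),
        }

    # ------------------------------------------------------------------
    def save(self, run_dir) -> None:
        """Write all artifacts plus a manifest to ``run_dir``."""
        run_dir = Path(run_dir)
        run_dir.mkdir(parents=True, exist_ok=True)
        with open(run_dir / "report.json", "w") as fh:
            json.dump(self.report.to_dict(), fh, indent=2)
        if self.report_strict is not None:
            with open(run_dir / "report_strict.json", "w") as fh:
                json.dump(self.report_strict.to_dict(), fh, indent=2)
        self.calls.to_csv(run_dir / "differential_calls.tsv", sep="\t", index=False)
        self.selection_counts.to_frame(self.feature_ids).to_csv(
            run_dir / "selection_counts.tsv", sep="\t", index=False
        )
        self.accv_surface.to_csv(run_dir / "accv_surface.tsv", sep="\t")
        if self.smote_error_table is not None:
            self.smote_error_table.to_csv(
                run_dir / "smote_errors.tsv", sep="\t", index=False
            )
        self.kopls_results.score_plot_frame().to_csv(
            run_dir / "scores.tsv", sep="\t", index=False
        )
        config_json = self.model.config.to_json()
        manifest = {
            "config": json.loads(config_json),
            "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
            "n_samples": int(self.y.size),
            "n_features": len(self.feature_ids),
            "selected_features": self.selected_features,
            "called_features": self.called["feature_id"].tolist(),
        }
        with open(run_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def run_full(table: PeakTable, config: PipelineConfig | None = None):
    """One-call pipeline: fit and return the results object."""
    return SyndromeStratifier(table, config).fit()
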