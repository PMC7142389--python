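"""Model/results front end for the coarse-to-fine pipeline.

`CoarseToFineVBM` is the statsmodels-style entry point: construct it from a
cohort (or directly from volumes), call :meth:`fit` to run screening, RFE and
the final linear SVM on the full sample, and use the returned results object
for weight maps, region reports, leave-one-out evaluation and a text summary.
"""

from __future__ import annotations

import numpy as np

from .volumes import CohortMatrix, Volume3D, to_matrix
from .screening import ScreeningConfig, ScreeningResult, screen
from .rfe import RFEConfig, RFERanking, SVMFit, fit_linear_svm, select_features
from .evaluation import EvaluationResult, loo_evaluate
from .report import RegionRecord, report_regions

__all__ = ["CoarseToFineVBM", "CoarseToFineVBMResults"]


class CoarseToFineVBM:
    """Coarse-to-fine discriminative model for two-group tissue maps.

    Parameters
    ----------
    cohort : CohortMatrix
        Subjects-by-voxels data with +1/-1 labels.
    screening : ScreeningConfig, optional
        Voxelwise t-test threshold and cluster-extent settings.
    rfe : RFEConfig, optional
        SVM penalty C, per-round elimination fraction and retained fraction.
    """

    def __init__(
        self,
        cohort: CohortMatrix,
        screening: ScreeningConfig | None = None,
        rfe: RFEConfig | None = None,
    ):
        self.cohort = cohort
        self.screening = screening or ScreeningConfig()
        self.rfe = rfe or RFEConfig()

    @classmethod
    def from_volumes(cls, volumes, labels, mask=None, screening=None, rfe=None):
        """Build the model straight from per-subject volumes and labels."""
        cohort = to_matrix(volumes, labels, mask if mask is not None else "all")
        return cls(cohort, screening=screening, rfe=rfe)

    def fit(self) -> "CoarseToFineVBMResults":
        """Run screen -> RFE -> final SVM on the full sample."""
        scr = screen(self.cohort, self.screening)
        if scr.n_selected == 0:
            raise ValueError(
                "screening left no surviving voxels; relax alpha or min_cluster"
            )
        reduced, ranking, provenance = select_features(self.cohort, scr, self.rfe)
        svm = fit_linear_svm(
            reduced.X, reduced.y, C=self.rfe.C, standardize=self.rfe.standardize
        )
        return CoarseToFineVBMResults(self, scr, reduced, ranking, provenance, svm)

    def evaluate(self, mode: str = "nested") -> EvaluationResult:
        """Leave-one-out evaluation of the whole pipeline (see loo_evaluate)."""
        return loo_evaluate(self.cohort, self.screening, self.rfe, mode=mode)


class CoarseToFineVBMResults:
    """Fitted pipeline: screening maps, RFE ranking and the final SVM."""

    def __init__(
        self,
        model: CoarseToFineVBM,
        screening: ScreeningResult,
        reduced: CohortMatrix,
        ranking: RFERanking,
        provenance: dict,
        svm: SVMFit,
    ):
        self.model = model
        self.screening = screening
        self.reduced = reduced
        self.ranking = ranking
        self.provenance = provenance
        self.svm = svm

    # -- derived quantities -------------------------------------------------

    @property
    def n_screened(self) -> int:
        return self.screening.n_selected

    @property
    def n_retained(self) -> int:
        return self.reduced.n_voxels

    @property
    def retained_columns(self) -> np.ndarray:
        """Retained voxel columns in the original cohort's column space."""
        return self.provenance["retained_columns"]

    def retained_mask(self) -> Volume3D:
        """Binary volume of the RFE-retained voxels."""
        mask = np.zeros(self.model.cohort.shape, dtype=np.uint8)
        i, j, k = self.reduced.mask_indices.T
        mask[i, j, k] = 1
        return Volume3D(mask, self.model.cohort.affine.copy())

    def weight_volume(self) -> Volume3D:
        """Final SVM weights scattered onto the grid (0 off the retained set)."""
        out = np.zeros(self.model.cohort.shape, dtype=np.float64)
        i, j, k = self.reduced.mask_indices.T
        out[i, j, k] = self.svm.weights
        return Volume3D(out, self.model.cohort.affine.copy())

    def regions(
        self,
        atlas: Volume3D | None = None,
        min_cluster: int | None = None,
    ) -> list[RegionRecord]:
        """Biomarker report over the retained voxel set."""
        cfg = self.model.screening
        return report_regions(
            self.retained_mask(),
            self.screening.t_map,
            atlas=atlas,
            min_cluster=cfg.min_cluster if min_cluster is None else min_cluster,
            connectivity=cfg.connectivity,
            p_threshold=cfg.alpha,
        )

    def loo(self, mode: str = "nested") -> EvaluationResult:
        return self.model.evaluate(mode=mode)

    # -- presentation -------------------------------------------------------

    def summary(self, evaluation: EvaluationResult | None = None) -> str:
        """Plain-text summary table (statsmodels style)."""
        cohort = self.model.cohort
        scfg, rcfg = self.model.screening, self.model.rfe
        lines = [
            "        Coarse-to-fine VBM discriminative analysis",
            "=" * 62,
            f"Subjects:             {cohort.n_subjects}  "
            f"(+1: {(cohort.y == 1).sum()}, -1: {(cohort.y == -1).sum()})",
            f"Voxels in mask:       {cohort.n_voxels}",
            f"Screening:            alpha={scfg.alpha}, min_cluster={scfg.min_cluster}, "
            f"connectivity={scfg.connectivity}",
            f"  surviving voxels:   {self.n_screened} "
            f"in {len(self.screening.clusters)} cluster(s)",
            f"RFE:                  C={rcfg.C}, elim/round={rcfg.elim_fraction}, "
            f"retain={rcfg.retain_fraction}",
            f"  retained voxels:    {self.n_retained} "
            f"({len(self.ranking.rounds)} elimination round(s))",
            f"Final SVM:            |support vectors|={self.svm.support.size}, "
            f"bias={self.svm.bias:+.4f}",
        ]
        if evaluation is not None:
            m = evaluation.metrics
            lines += [
                "-" * 62,
                f"Leave-one-out ({evaluation.mode} selection):",
                f"  ACC={m.acc:.4f}  SN={m.sn:.4f}  SP={m.sp:.4f}",
                f"  GM={m.gm:.4f}  DM={m.dm:.4f}  F2M={m.f2m:.4f}  AUC={m.auc:.4f}",
            ]
        lines.append("=" * 62)
        return "\n".join(lines)
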