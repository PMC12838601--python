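"""Model/Results interface over the full pipeline.

``LymphomaMipModel`` is built from a labeled cohort (typically the synthetic
phantom, or anything matching its case interface): it runs the whole image
and clinical preprocessing chain once, with normalization statistics fitted
on the training split only.  ``fit`` trains the fusion network and returns a
``LymphomaMipResults`` carrying per-case scores, per-cohort metric reports
with bootstrap CIs, cohort comparisons, the training history, and Grad-CAM
explanations.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd

from .evalstats import (
    MetricReport,
    bootstrap_auc_diff_test,
    delong_test_unpaired,
    metric_report,
)
from .explain import gradcam, localization_score, project_lesion_mask
from .nn.network import MipFusionNetwork, ModelConfig, build_model
from .nn.training import TrainConfig, predict, train
from .phantom import LabeledCase
from .preproc import (
    TrainStats,
    encode_clinical,
    fit_train_stats,
    prepare_model_images,
)

logger = logging.getLogger("petmip.api")

COHORTS = ("train", "internal_test", "external_test")


class LymphomaMipModel:
    """Multimodal MIP + clinical classifier over a labeled cohort.

    Parameters
    ----------
    cases
        Labeled cases with ``volume``, ``meta``, ``clinical``, ``label``,
        ``cohort`` attributes (see :class:`petmip.phantom.LabeledCase`).
    image_size
        Side length of the square model-input images.  310 matches the
        full-scale pipeline; smaller values keep CPU training fast.
    model_config
        Network architecture; ``clinical_input_dim`` and ``n_manufacturers``
        are filled in from the data.
    """

    def __init__(
        self,
        cases: list[LabeledCase],
        image_size: int = 64,
        model_config: ModelConfig | None = None,
        val_fraction: float = 0.2,
    ):
        if not cases:
            raise ValueError("no cases supplied")
        self.cases = list(cases)
        self.image_size = image_size
        self.val_fraction = val_fraction

        train_cases = [c for c in self.cases if c.cohort == "train"]
        if not train_cases:
            raise ValueError("cohort contains no training cases")
        self.train_stats: TrainStats = fit_train_stats(
            [c.clinical for c in train_cases],
            cohorts=[c.cohort for c in train_cases],
        )
        self._data = self._prepare(self.cases)
        n_manufacturers = int(max(c.meta.manufacturer for c in train_cases)) + 1

        cfg = model_config or ModelConfig()
        self.model_config = replace(
            cfg,
            clinical_input_dim=int(self._data["clinical"].shape[1]),
            n_manufacturers=n_manufacturers,
        )

    # ------------------------------------------------------------------
    def _prepare(self, cases: list[LabeledCase]) -> dict:
        ant, lat, clin = [], [], []
        for case in cases:
            imgs = prepare_model_images(case.volume, case.meta, target=self.image_size)
            ant.append(imgs["anterior"].astype(np.float32))
            lat.append(imgs["lateral"].astype(np.float32))
            clin.append(encode_clinical(case.clinical, self.train_stats))
        return {
            "anterior": np.stack(ant),
            "lateral": np.stack(lat),
            "clinical": np.stack(clin).astype(np.float32),
            "s": np.array([c.meta.manufacturer for c in cases], dtype=int),
            "y": np.array([c.label for c in cases], dtype=int),
            "cohort": np.array([c.cohort for c in cases]),
            "case_id": np.array([c.case_id for c in cases]),
        }

    def _cohort_data(self, cohort: str) -> dict:
        idx = np.flatnonzero(self._data["cohort"] == cohort)
        return {k: v[idx] for k, v in self._data.items()}

    def case_batch(self, case_index: int) -> dict:
        """Single-case batch dict (for Grad-CAM and spot predictions)."""
        return {
            k: self._data[k][case_index : case_index + 1]
            for k in ("anterior", "lateral", "clinical", "s")
        }

    # ------------------------------------------------------------------
    def fit(self, train_config: TrainConfig | None = None) -> "LymphomaMipResults":
        """Train the network and score every cohort.

        A validation split (stratified by label) is carved out of the training
        cases for early stopping and scheduling; internal and external test
        cohorts are never touched during optimization.  External cases from a
        manufacturer absent in training are scored through the SCN mean-row
        fallback (logged).
        """
        tcfg = train_config or TrainConfig()
        dtrain_all = self._cohort_data("train")
        n = len(dtrain_all["y"])
        rng = np.random.default_rng(tcfg.seed)
        val_idx: list[int] = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(dtrain_all["y"] == cls)
            perm = rng.permutation(cls_idx)
            n_val = max(1, int(round(self.val_fraction * len(cls_idx))))
            val_idx += perm[:n_val].tolist()
        val_mask = np.zeros(n, dtype=bool)
        val_mask[val_idx] = True
        dtrain = {k: v[~val_mask] for k, v in dtrain_all.items()}
        dval = {k: v[val_mask] for k, v in dtrain_all.items()}

        network = build_model(self.model_config, seed=tcfg.seed)
        history = train(network, dtrain, dval, tcfg)

        rows = []
        trained_s = set(np.unique(dtrain["s"]).tolist())
        for cohort in COHORTS:
            data = self._cohort_data(cohort)
            if len(data["y"]) == 0:
                continue
            unseen = set(np.unique(data["s"]).tolist()) - trained_s
            policy = "mean" if unseen else "error"
            if unseen:
                logger.info(
                    "cohort %s has untrained manufacturers %s; using SCN mean-row fallback",
                    cohort, sorted(unseen),
                )
            scores = predict(network, data, unseen_manufacturer=policy)
            for cid, sc, y, s in zip(data["case_id"], scores, data["y"], data["s"]):
                rows.append(
                    {"case_id": cid, "score": float(sc), "label": int(y),
                     "manufacturer": int(s), "cohort": cohort}
                )
        predictions = pd.DataFrame(rows)
        return LymphomaMipResults(self, network, history, predictions, tcfg)


class LymphomaMipResults:
    """Fitted model: scores, metrics, comparisons, explanations."""

    def __init__(
        self,
        model: LymphomaMipModel,
        network: MipFusionNetwork,
        history: dict,
        predictions: pd.DataFrame,
        train_config: TrainConfig,
    ):
        self.model = model
        self.network = network
        self.history = history
        self.predictions = predictions
        self.train_config = train_config

    def _cohort_scores(self, cohort: str) -> tuple[np.ndarray, np.ndarray]:
        sub = self.predictions[self.predictions["cohort"] == cohort]
        if sub.empty:
            raise ValueError(f"no predictions for cohort {cohort!r}")
        return sub["score"].to_numpy(), sub["label"].to_numpy()

    def metric_report(
        self, cohort: str = "internal_test", threshold: float = 0.5,
        B: int = 1000, seed: int = 0,
    ) -> MetricReport:
        scores, labels = self._cohort_scores(cohort)
        return metric_report(scores, labels, threshold=threshold, B=B, seed=seed)

    def auc(self, cohort: str = "internal_test") -> float:
        from .evalstats import roc_auc

        return roc_auc(*self._cohort_scores(cohort))

    def compare_cohorts(
        self, cohort_a: str = "internal_test", cohort_b: str = "external_test"
    ) -> dict:
        """Unpaired DeLong test between two independent cohorts."""
        sa, ya = self._cohort_scores(cohort_a)
        sb, yb = self._cohort_scores(cohort_b)
        auc_a, auc_b, z, p = delong_test_unpaired(sa, ya, sb, yb)
        return {"auc_a": auc_a, "auc_b": auc_b, "z": z, "p": p,
                "cohorts": (cohort_a, cohort_b)}

    def compare_with(
        self, other: "LymphomaMipResults", cohort: str = "internal_test",
        B: int = 1000, seed: int = 0,
    ) -> dict:
        """Paired bootstrap AUC-difference test against another fitted model
        scored on the same cases."""
        mine = self.predictions[self.predictions["cohort"] == cohort].set_index("case_id")
        theirs = other.predictions[other.predictions["cohort"] == cohort].set_index("case_id")
        if not mine.index.equals(theirs.index):
            theirs = theirs.reindex(mine.index)
            if theirs["score"].isna().any():
                raise ValueError("paired comparison requires identical case sets")
        delta, ci, p = bootstrap_auc_diff_test(
            mine["score"].to_numpy(), theirs["score"].to_numpy(),
            mine["label"].to_numpy(), B=B, seed=seed,
        )
        return {"delta_auc": delta, "ci": ci, "p": p, "cohort": cohort}

    def gradcam(self, case_index: int, target_class: int | None = None) -> dict:
        """Grad-CAM maps for one case (by index into the model's case list)."""
        case = self.model.cases[case_index]
        batch = self.model.case_batch(case_index)
        if target_class is None:
            target_class = case.label
        fallback = int(batch["s"][0]) >= self.network.config.n_manufacturers
        return gradcam(self.network, batch, target_class=target_class, fallback=fallback)

    def gradcam_localization(self, case_index: int, view: str = "anterior",
                             top_frac: float = 0.1) -> float:
        """Fraction of the top heat-map pixels inside the true lesion mask."""
        case = self.model.cases[case_index]
        maps = self.gradcam(case_index)
        mask2d = project_lesion_mask(
            case.lesion_mask, view, self.model.image_size, case.volume.spacing_mm
        )
        return localization_score(maps[view], mask2d, top_frac=top_frac)

    def summary(self, B: int = 200, seed: int = 0) -> str:
        """Text table of per-cohort metrics with bootstrap CIs."""
        lines = [
            "Multimodal PET-MIP + clinical classifier",
            f"  backbone={self.network.config.backbone}  views={self.network.config.views}"
            f"  scn={'on' if self.network.config.use_scn else 'off'}"
            f"  clinical={'on' if self.network.config.use_clinical else 'off'}",
            f"  best epoch {self.history['best_epoch']} / stopped {self.history['stopped_epoch']}",
            "",
            f"  {'cohort':<15}{'n':>5}{'AUC':>8}{'95% CI':>16}{'MCC':>7}{'Sens':>7}{'Spec':>7}",
        ]
        for cohort in self.predictions["cohort"].unique():
            if cohort == "train":
                continue
            rep = self.metric_report(cohort, B=B, seed=seed)
            lines.append(
                f"  {cohort:<15}{rep.n:>5}{rep.auc:>8.3f}"
                f"  ({rep.auc_ci[0]:.3f},{rep.auc_ci[1]:.3f})"
                f"{rep.mcc:>7.3f}{rep.sensitivity:>7.3f}{rep.specificity:>7.3f}"
            )
        return "\n".join(lines)
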