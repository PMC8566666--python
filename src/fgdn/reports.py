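"""Evaluation report containers shared by the I/O and evaluation layers."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class FoldResult:
    """Metrics for one held-out fold (or site), all on a 0-100 scale.

    ``auc`` is ``None`` when the fold's truth contains a single class and the
    ranking statistic is undefined.
    """

    fold_id: str
    acc: float
    auc: float | None
    sensitivity: float | None
    specificity: float | None
    n_test: int

    def to_dict(self) -> dict:
        return {
            "fold_id": self.fold_id,
            "acc": self.acc,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n_test": self.n_test,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FoldResult":
        return cls(
            fold_id=d["fold_id"],
            acc=d["acc"],
            auc=d["auc"],
            sensitivity=d["sensitivity"],
            specificity=d["specificity"],
            n_test=d["n_test"],
        )


def _mean_sd(values: list[float]) -> tuple[float, float]:
    import numpy as np

    a = np.asarray(values, dtype=float)
    return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0


@dataclass
class EvalReport:
    """Per-fold metrics plus mean (SD) summaries for one experiment."""

    experiment: str  # "cv" | "loso" | "learning_curve" | "regions"
    folds: list[FoldResult]
    seed: int
    extra: dict = field(default_factory=dict)

    def summary(self) -> dict:
        """Mean and sample SD per metric, skipping undefined (None) entries."""
        out: dict[str, dict[str, float]] = {}
        for metric in ("acc", "auc", "sensitivity", "specificity"):
            vals = [getattr(f, metric) for f in self.folds if getattr(f, metric) is not None]
            if not vals:
                out[metric] = {"mean": None, "sd": None}
                continue
            mean, sd = _mean_sd(vals)
            out[metric] = {"mean": mean, "sd": sd}
        return out

    def to_dict(self) -> dict:
        return {
            "experiment": self.experiment,
            "seed": self.seed,
            "folds": [f.to_dict() for f in self.folds],
            "summary": self.summary(),
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EvalReport":
        return cls(
            experiment=d["experiment"],
            folds=[FoldResult.from_dict(f) for f in d["folds"]],
            seed=d["seed"],
            extra=d.get("extra", {}),
        )
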