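"""Model-style facade over the full transfer-classification pipeline.

`TransferPipeline` is constructed from two recorded (or simulated)
sessions plus a configuration; `fit()` runs preprocessing, feature
extraction, fusion, grid-searched training and held-out evaluation, and
returns a `TransferResults` object carrying the metrics, the confusion
matrix and a printable `summary()` table.

Feature "cases" select what enters the classifier:

* ``"tif"`` — channel-based scattering features only;
* ``"bcf:<metric>"`` — connectivity features only (pc, pearson or pli);
* ``"tif+pc"`` / ``"tif+pearson"`` / ``"tif+pli"`` — serial fusion of
  both sources.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .connectivity import bcf_features
from .evaluation import (
    ConfusionMatrix,
    TrainConfig,
    TrainedModel,
    accuracy,
    cohen_kappa,
    cst_split,
    evaluate,
    precision_recall,
    sst_split,
    train_model,
)
from .features import FeatureMatrix, fuse
from .preprocess import EpochSet, TrialSet, preprocess
from .scattering import ScatteringConfig, tif_extract

CASES = ("tif", "bcf:pc", "bcf:pearson", "bcf:pli", "tif+pc", "tif+pearson", "tif+pli")


@dataclass
class PipelineConfig:
    """Every tunable default of the pipeline in one place."""

    band: tuple[float, float] = (8.0, 30.0)
    filter_order: int = 4
    baseline_window: tuple[float, float] | None = (0.0, 2.0)
    analysis_window: tuple[float, float] = (2.5, 5.0)
    drop_artifacts: bool = True
    tif_subset: object = "default11"
    scattering: ScatteringConfig | None = None
    training: TrainConfig = field(default_factory=TrainConfig)
    classes: tuple[str, ...] | None = None  # subset for e.g. three-class mode

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["tif_subset"] = list(d["tif_subset"]) if not isinstance(
            self.tif_subset, str
        ) else self.tif_subset
        with open(path, "w") as f:
            yaml.safe_dump(d, f)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as f:
            d = yaml.safe_load(f)
        if d.get("scattering"):
            d["scattering"] = ScatteringConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d["scattering"].items()
                }
            )
        if d.get("training"):
            d["training"] = TrainConfig(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d["training"].items()
                }
            )
        for key in ("band", "baseline_window", "analysis_window", "classes"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _case_parts(case: str) -> list[str]:
    case = case.lower()
    if case not in CASES:
        raise ValueError(f"case must be one of {CASES}, got {case!r}")
    parts = []
    if case.startswith("tif"):
        parts.append("tif")
    if ":" in case or "+" in case:
        parts.append(case.split(":" if ":" in case else "+")[1])
    return parts


def case_features(epochs: EpochSet, case: str, cfg: PipelineConfig) -> FeatureMatrix:
    """Extract the feature matrix a given case feeds to the classifier."""
    parts = []
    for kind in _case_parts(case):
        if kind == "tif":
            scfg = cfg.scattering or ScatteringConfig(fs=epochs.fs)
            parts.append(tif_extract(epochs, scfg, subset=cfg.tif_subset))
        else:
            parts.append(bcf_features(epochs, kind))
    out = parts[0]
    for extra in parts[1:]:
        out = fuse(out, extra)
    return out


@dataclass
class TransferResults:
    """Fitted-pipeline results: metrics, diagnostics and summary table."""

    strategy: str
    case: str
    validation_accuracy: float
    test_accuracy: float
    kappa: float
    precision: float
    recall: float
    confusion: ConfusionMatrix
    model: TrainedModel
    n_train: int
    n_test: int

    def metrics(self) -> dict[str, float]:
        return {
            "acc_val": self.validation_accuracy,
            "acc_test": self.test_accuracy,
            "kappa_test": self.kappa,
            "prec_test": self.precision,
            "rec_test": self.recall,
        }

    def summary(self) -> str:
        lines = [
            "Transfer classification results",
            "=" * 46,
            f"{'Strategy':<28}{self.strategy.upper():>18}",
            f"{'Feature case':<28}{self.case:>18}",
            f"{'Training epochs':<28}{self.n_train:>18d}",
            f"{'Test epochs':<28}{self.n_test:>18d}",
            f"{'Selected features (S)':<28}{self.model.s:>18d}",
            f"{'SVM C':<28}{self.model.c:>18.4g}",
            f"{'SVM gamma':<28}{self.model.gamma:>18.4g}",
            "-" * 46,
            f"{'Validation accuracy (%)':<28}{self.validation_accuracy:>18.2f}",
            f"{'Test accuracy (%)':<28}{self.test_accuracy:>18.2f}",
            f"{'Cohen kappa':<28}{self.kappa:>18.2f}",
            f"{'Macro precision':<28}{self.precision:>18.2f}",
            f"{'Macro recall':<28}{self.recall:>18.2f}",
            "=" * 46,
            "Confusion matrix (rows true, cols predicted):",
        ]
        classes = [str(c) for c in self.confusion.classes]
        lines.append(" " * 6 + "".join(f"{c:>6}" for c in classes))
        for cls, row in zip(classes, self.confusion.counts):
            lines.append(f"{cls:>6}" + "".join(f"{v:>6d}" for v in row))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "case": self.case,
            **self.metrics(),
            "hyperparameters": {"C": self.model.c, "gamma": self.model.gamma, "S": int(self.model.s)},
            "confusion": self.confusion.counts.tolist(),
            "classes": [str(c) for c in self.confusion.classes],
        }


class TransferPipeline:
    """End-to-end pipeline bound to two sessions of one subject.

    Parameters
    ----------
    session1, session2 : TrialSet
        Raw labelled trials of the two recording sessions.
    strategy : {"sst", "cst"}
        Session-to-session or calibration-session transfer.
    case : str
        Feature case (see module docstring).
    config : PipelineConfig
        All preprocessing/feature/training settings.

    Examples
    --------
    >>> from mibci import simulate, TransferPipeline
    >>> cfg = simulate.ParadigmConfig(trials_per_class=12)
    >>> s1 = simulate.to_trial_set(simulate.generate_session(cfg, seed=1, session_id="S1"))
    >>> s2 = simulate.to_trial_set(simulate.generate_session(cfg, seed=2, session_id="S2"))
    >>> results = TransferPipeline(s1, s2, strategy="sst", case="tif+pc").fit()  # doctest: +SKIP
    >>> print(results.summary())  # doctest: +SKIP
    """

    def __init__(
        self,
        session1: TrialSet,
        session2: TrialSet,
        strategy: str = "sst",
        case: str = "tif+pc",
        config: PipelineConfig | None = None,
    ) -> None:
        if strategy not in ("sst", "cst"):
            raise ValueError("strategy must be 'sst' or 'cst'")
        self.session1 = session1
        self.session2 = session2
        self.strategy = strategy
        self.case = case
        self.config = config or PipelineConfig()

    def _restrict_classes(self, ts: TrialSet) -> TrialSet:
        if self.config.classes is None:
            return ts
        keep = np.isin(ts.labels, list(self.config.classes))
        return TrialSet(
            data=ts.data[:, :, keep],
            fs=ts.fs,
            montage=list(ts.montage),
            labels=ts.labels[keep],
            artifact_flags=ts.artifact_flags[keep],
            session_id=ts.session_id,
            time_zero=ts.time_zero,
        )

    def fit(self) -> TransferResults:
        return compare_cases(
            self.session1,
            self.session2,
            cases=(self.case,),
            strategy=self.strategy,
            config=self.config,
        )[self.case]


def compare_cases(
    session1: TrialSet,
    session2: TrialSet,
    cases=("tif", "tif+pc"),
    strategy: str = "sst",
    config: PipelineConfig | None = None,
) -> dict[str, "TransferResults"]:
    """Fit several feature cases on the same pair of sessions.

    Preprocessing and the TIF/BCF extractions are shared across cases,
    so comparing e.g. ``"tif"`` against ``"tif+pc"`` costs one scattering
    pass, not two.
    """
    cfg = config or PipelineConfig()
    pipe = TransferPipeline(session1, session2, strategy=strategy,
                            case=cases[0], config=cfg)
    epochs = []
    for ts in (session1, session2):
        ts = pipe._restrict_classes(ts)
        epochs.append(
            preprocess(
                ts,
                band=cfg.band,
                order=cfg.filter_order,
                baseline_window=cfg.baseline_window,
                window=cfg.analysis_window,
                drop_artifacts=cfg.drop_artifacts,
            )
        )
    e1, e2 = epochs
    plan = sst_split(e1, e2) if strategy == "sst" else cst_split(e1, e2)

    part_cache: dict[str, tuple[FeatureMatrix, FeatureMatrix]] = {}

    def parts_for(kind: str) -> tuple[FeatureMatrix, FeatureMatrix]:
        if kind not in part_cache:
            if kind == "tif":
                scfg = cfg.scattering or ScatteringConfig(fs=e1.fs)
                part_cache[kind] = (
                    tif_extract(e1, scfg, subset=cfg.tif_subset),
                    tif_extract(e2, scfg, subset=cfg.tif_subset),
                )
            else:
                part_cache[kind] = (bcf_features(e1, kind), bcf_features(e2, kind))
        return part_cache[kind]

    results: dict[str, TransferResults] = {}
    for case in cases:
        f1 = f2 = None
        for kind in _case_parts(case):
            p1, p2 = parts_for(kind)
            f1 = p1 if f1 is None else fuse(f1, p1)
            f2 = p2 if f2 is None else fuse(f2, p2)
        values = np.vstack([f1.values, f2.values])
        labels = np.concatenate([f1.labels, f2.labels])
        train = FeatureMatrix(
            values=values[plan.train_ids], tags=f1.tags, labels=labels[plan.train_ids]
        )
        test = FeatureMatrix(
            values=values[plan.test_ids], tags=f1.tags, labels=labels[plan.test_ids]
        )
        model = train_model(train, cfg.training)
        cm = evaluate(model, test)
        prec, rec = precision_recall(cm)
        results[case] = TransferResults(
            strategy=strategy,
            case=case,
            validation_accuracy=model.validation_accuracy,
            test_accuracy=accuracy(cm),
            kappa=cohen_kappa(cm),
            precision=prec,
            recall=rec,
            confusion=cm,
            model=model,
            n_train=train.n_epochs,
            n_test=test.n_epochs,
        )
    return results
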