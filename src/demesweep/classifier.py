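"""Two-stage sweep classification with boosted decision trees.

The protocol mirrors how supervised sweep classifiers are deployed in
practice. For each training *stage* (a sweep photographed at 60%, 80% or
99.5% completion, at global fixation, or 1,000 generations later, plus a
mixed pool) a *predictor pair* is trained on per-window summary statistics:

* predictor 1 separates neutral (y = 0) from sweep (y = 1, hard and soft
  pooled); its decision thresholds are not the model default but empirical
  quantiles of the scores of an independent neutral-background set, fixing
  the false positive rate at 5%, 1% or 0.1%;
* predictor 2 separates soft (y = 0) from hard (y = 1) sweeps and always
  uses the neutral threshold 0.5 to avoid an a-priori bias towards either
  sweep type.

A sample below the stage-1 threshold is "neutral"; above it, it is "soft"
or "hard" according to predictor 2. Cross-testing predictor pairs against
sweep samples of mismatched stages exposes the temporal softening/hardening
misclassifications; applying them to the 100-300 kb flank instead of the
sweep-centred 200 kb exposes the soft-shoulder effect.

Features are the window tracks of the in-house statistics (five SFS, four
haplotype-spectrum, and the iHS/nSL significance proportions) over the
first 11 windows (200-kb mode) or all 51 (600-kb mode); missing windows are
imputed by the neutral-background mean. The boosted-tree backend is
deliberately generic (fixed hyper-parameters, explicit seed): the protocol
and its directional phenomena, not any particular published predictor, are
the contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier

from .io_formats import HaplotypeSample, WindowGrid, make_windows
from .sumstats import NormalisationTable, ScoreTrack, score_sample
from .genomic_sim import TrainingSet

__all__ = [
    "CLASSIFIER_STATS",
    "Featurizer",
    "PredictorPair",
    "train_pair",
    "classify",
    "cross_test",
    "classification_report",
]

CLASSIFIER_STATS = (
    "theta_pi",
    "theta_w",
    "theta_h",
    "tajima_d",
    "faywu_h",
    "n_hap",
    "H1",
    "H12",
    "H2_H1",
    "ihs_prop",
    "nsl_prop",
)

#: boosted-tree backend hyper-parameters, fixed and recorded
GBT_PARAMS = dict(n_estimators=150, max_depth=3, learning_rate=0.1, subsample=0.8)


class Featurizer:
    """Maps samples to fixed-length window-statistic vectors.

    ``mode`` is "200kb" (first 11 windows, sweep-centred) or "600kb" (all
    51). ``offset_bp`` shifts the scanned frame right, e.g. 100,000 scans
    the 100-300 kb flank with the same 11-window geometry (the soft-shoulder
    probe). iHS/nSL require neutral-background normalisation tables.
    """

    def __init__(
        self,
        mode: str = "200kb",
        ihs_table: NormalisationTable | None = None,
        nsl_table: NormalisationTable | None = None,
        region_length: float = 600_000.0,
        offset_bp: float = 0.0,
    ) -> None:
        if mode not in ("200kb", "600kb"):
            raise ValueError("mode must be '200kb' or '600kb'")
        self.mode = mode
        self.offset_bp = offset_bp
        full = make_windows(region_length, 100_000.0, 10_000.0)
        if mode == "200kb":
            windows = [
                (s + offset_bp, e + offset_bp)
                for s, e in full.windows
                if e <= 200_000.0
            ]
            self.grid = WindowGrid(region_length, 100_000.0, 10_000.0, windows)
        else:
            if offset_bp:
                raise ValueError("offset applies to 200kb mode only")
            self.grid = full
        self.ihs_table = ihs_table
        self.nsl_table = nsl_table
        self.stats = CLASSIFIER_STATS
        self.n_features = len(self.stats) * self.grid.n_windows

    def feature_names(self) -> list[str]:
        return [f"{s}_w{w}" for s in self.stats for w in range(self.grid.n_windows)]

    def features(self, sample: HaplotypeSample) -> np.ndarray:
        """Raw (unimputed) feature vector; NaN marks missing windows."""
        lo = self.offset_bp
        hi = self.grid.windows[-1][1]
        tracks = score_sample(
            sample,
            grid=self.grid,
            stats=self.stats,
            ihs_table=self.ihs_table,
            nsl_table=self.nsl_table,
            restrict_pivots=(lo, hi),
        )
        return np.concatenate([tracks[s].values for s in self.stats])

    def matrix(self, samples: Iterable[HaplotypeSample]) -> np.ndarray:
        return np.array([self.features(s) for s in samples])


def impute(
    X: np.ndarray, nb_means: np.ndarray, max_missing_frac: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """NB-mean imputation of missing features.

    Returns the imputed matrix and a keep-mask; samples with more than half
    of their entries missing are dropped (flagged False) with a warning.
    """
    X = np.array(X, dtype=float)
    missing = np.isnan(X)
    keep = missing.mean(axis=1) <= max_missing_frac
    if (~keep).any():
        warnings.warn(f"{int((~keep).sum())} samples dropped: >50% missing features")
    X[missing] = np.broadcast_to(nb_means, X.shape)[missing]
    return X, keep


def nb_feature_means(nb_X: np.ndarray) -> np.ndarray:
    """Per-feature neutral-background means used for imputation (features
    that are missing in every NB sample impute to 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        m = np.nanmean(np.asarray(nb_X, dtype=float), axis=0)
    return np.where(np.isnan(m), 0.0, m)


@dataclass
class PredictorPair:
    """Stage-labelled pair: sweep detector + hard/soft discriminator."""

    stage: str
    detector: GradientBoostingClassifier
    discriminator: GradientBoostingClassifier
    thresholds: dict[float, float]  # nominal FPR -> detector score cutoff
    nb_means: np.ndarray
    mode: str
    hard_soft_threshold: float = 0.5
    seed: int = 0

    def detector_scores(self, X: np.ndarray) -> np.ndarray:
        return self.detector.predict_proba(X)[:, 1]

    def discriminator_scores(self, X: np.ndarray) -> np.ndarray:
        return self.discriminator.predict_proba(X)[:, 1]


def _fit_gbt(X: np.ndarray, y: np.ndarray, seed: int) -> GradientBoostingClassifier:
    clf = GradientBoostingClassifier(random_state=seed, **GBT_PARAMS)
    clf.fit(X, y)
    return clf


def train_pair(
    stage: str,
    neutral_X: np.ndarray,
    hard_X: np.ndarray,
    soft_X: np.ndarray,
    nb_threshold_X: np.ndarray,
    seed: int,
    mode: str = "200kb",
    fprs: Sequence[float] = (0.05, 0.01, 0.001),
) -> PredictorPair:
    """Train one predictor pair from featurized training material.

    ``nb_threshold_X`` must be an independent neutral set (not the training
    neutrals): its detector-score distribution calibrates the FPR cutoffs as
    upper-tail order statistics.
    """
    nb_means = nb_feature_means(neutral_X)
    neutral_X, _ = impute(neutral_X, nb_means)
    hard_X, _ = impute(hard_X, nb_means)
    soft_X, _ = impute(soft_X, nb_means)
    nb_thr_X, _ = impute(nb_threshold_X, nb_means)

    sweep_X = np.vstack([hard_X, soft_X])
    X1 = np.vstack([neutral_X, sweep_X])
    y1 = np.concatenate([np.zeros(len(neutral_X)), np.ones(len(sweep_X))])
    detector = _fit_gbt(X1, y1, seed)

    X2 = np.vstack([soft_X, hard_X])
    y2 = np.concatenate([np.zeros(len(soft_X)), np.ones(len(hard_X))])
    discriminator = _fit_gbt(X2, y2, seed + 1)

    nb_scores = detector.predict_proba(nb_thr_X)[:, 1]
    if np.ptp(nb_scores) == 0 or np.ptp(detector.predict_proba(X1)[:, 1]) == 0:
        raise ValueError("degenerate training: detector scores have no spread")
    srt = np.sort(nb_scores)
    thresholds = {}
    for f in fprs:
        k = max(1, int(np.floor(f * nb_scores.size)))
        thresholds[float(f)] = float(srt[-k])
    return PredictorPair(
        stage=stage,
        detector=detector,
        discriminator=discriminator,
        thresholds=thresholds,
        nb_means=nb_means,
        mode=mode,
        seed=seed,
    )


def classify(
    X: np.ndarray, pair: PredictorPair, fpr: float = 0.01
) -> np.ndarray:
    """Three-way labels for featurized samples.

    Below the stage-1 cutoff: "neutral" (regardless of the second score);
    at/above it: "soft" if the hard-vs-soft score is below 0.5, else "hard".
    """
    X, _ = impute(X, pair.nb_means)
    s1 = pair.detector_scores(X)
    s2 = pair.discriminator_scores(X)
    cut = pair.thresholds[float(fpr)]
    out = np.where(
        s1 < cut, "neutral", np.where(s2 < pair.hard_soft_threshold, "soft", "hard")
    )
    return out


def classification_report(labels: np.ndarray) -> dict[str, float]:
    n = len(labels)
    return {
        c: float(np.mean(labels == c)) if n else float("nan")
        for c in ("neutral", "soft", "hard")
    }


def cross_test(
    pairs: Sequence[PredictorPair],
    test_sets: Mapping[str, Mapping[str, np.ndarray]],
    fpr: float = 0.01,
) -> pd.DataFrame:
    """Full cross-testing matrix: every predictor pair against every stage's
    hard and soft test sets; one row per (pair, test stage, class) with the
    neutral/soft/hard proportions (summing to 1)."""
    rows = []
    for pair in pairs:
        for test_stage, classes in test_sets.items():
            for true_class, X in classes.items():
                rep = classification_report(classify(X, pair, fpr))
                rows.append(
                    dict(
                        predictor=pair.stage,
                        test_stage=test_stage,
                        true_class=true_class,
                        **{f"prop_{k}": v for k, v in rep.items()},
                    )
                )
    return pd.DataFrame(rows)
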