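"""Arm-level aneuploidy detection from repeat-amplicon counts.

A single primer pair amplifies thousands of repeat loci spread over the 39
non-acrocentric autosomal arms; copy-number change of an arm shifts that
arm's share of the total read count.  Detection proceeds in three steps:

1. **Arm z-scores.**  Each sample's per-arm share of total depth is
   standardised against a euploid reference (per-arm mean and spread across
   euploid control profiles), giving a 39-vector of z-scores.  An arm is
   called gained/lost when |z| exceeds a threshold calibrated to a 1%
   per-arm call rate on euploid training data.
2. **Genome-wide score.**  A support-vector machine (RBF kernel) trained on
   3,150 synthetic low-neoplastic-fraction aneuploid samples and 677 euploid
   samples separates the two classes.  The SVM sees the 39 arm z-scores
   through an order-statistic map (|z| sorted descending): aneuploidy means
   "some arms are extreme", irrespective of which, and sorting aligns that
   signal onto fixed coordinates where a kernel can see it.  Decision values
   are mapped to a [0, 1] genome-wide aneuploidy score by Platt scaling
   fitted on out-of-fold decision values.
3. **Decision rule.**  A sample is aneuploidy-positive when the score is
   strictly greater than 0.7 *and* at least one arm is called gained or lost.

:class:`AneuploidyModel` holds the euploid controls and configuration;
:meth:`AneuploidyModel.fit` builds the training set, trains and calibrates,
and returns :class:`AneuploidyResults`, which scores samples, traces
detection-limit curves, and round-trips through a single JSON file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics.pairwise import rbf_kernel
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .panel import NON_ACROCENTRIC_ARMS, uniform_arm_map, validate_arm_map

__all__ = [
    "AneuploidyConfig",
    "ArmZProfile",
    "AneuploidyCall",
    "arm_shares",
    "arm_zscores",
    "build_training_set",
    "AneuploidyModel",
    "AneuploidyResults",
    "load_model",
]

FORMAT_VERSION = 1


@dataclass
class AneuploidyConfig:
    """Training and decision parameters for the aneuploidy classifier."""

    n_aneuploid: int = 3150
    n_euploid: int = 677
    fraction_range: tuple[float, float] = (0.005, 0.10)
    max_events: int = 5
    arm_call_euploid_rate: float = 0.01  # target per-arm call rate on euploid data
    platt_euploid_weight: float = 8.0    # specificity-first weighting of the calibration
    score_threshold: float = 0.7
    kernel: str = "rbf"
    svm_c: float = 1.0
    depth_median: float = 8e6
    depth_sigma: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.fraction_range
        if not 0 < lo < hi <= 1:
            raise ValueError(f"fraction_range invalid: {self.fraction_range}")
        if self.kernel not in ("rbf", "linear"):
            raise ValueError(f"kernel must be rbf or linear, got {self.kernel!r}")
        if not 0 < self.score_threshold < 1:
            raise ValueError("score_threshold must lie in (0, 1)")
        if self.n_aneuploid < 2 or self.n_euploid < 2:
            raise ValueError("need at least two training samples per class")


@dataclass
class ArmZProfile:
    """Per-arm z-scores and gain/loss calls for one sample."""

    z: pd.Series          # index: the 39 arms
    calls: pd.Series      # "gain" | "loss" | "neutral"
    total_depth: int

    def n_called(self) -> int:
        return int((self.calls != "neutral").sum())


@dataclass
class AneuploidyCall:
    """Genome-wide score plus arm calls and the combined decision."""

    score: float
    arms: ArmZProfile
    positive: bool


def decision_rule(score: float, n_arm_calls: int, score_threshold: float = 0.7) -> bool:
    """Positive iff score strictly exceeds the threshold AND >=1 arm is called."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must lie in [0, 1], got {score}")
    return score > score_threshold and n_arm_calls >= 1


def arm_shares(profile: pd.Series, arm_map: pd.DataFrame) -> pd.Series:
    """Per-arm share of total depth (the 39 shares sum to 1)."""
    unknown = profile.index.difference(arm_map.index)
    if len(unknown):
        raise ValueError(f"unknown loci: {list(unknown[:5])}")
    total = profile.sum()
    if total <= 0:
        raise ValueError("profile has zero total depth")
    arms = arm_map.loc[profile.index, "arm"]
    shares = profile.groupby(arms).sum() / total
    return shares.reindex(NON_ACROCENTRIC_ARMS, fill_value=0.0)


def arm_zscores(
    profile: pd.Series,
    arm_map: pd.DataFrame,
    ref_mean: pd.Series,
    ref_sd: pd.Series,
    arm_call_threshold: float,
) -> ArmZProfile:
    """Standardise a locus-count profile against the euploid reference."""
    shares = arm_shares(profile, arm_map)
    z = (shares - ref_mean) / ref_sd
    calls = pd.Series(
        np.where(z > arm_call_threshold, "gain",
                 np.where(z < -arm_call_threshold, "loss", "neutral")),
        index=z.index,
    )
    return ArmZProfile(z=z, calls=calls, total_depth=int(profile.sum()))


def _sorted_abs(Z: np.ndarray) -> np.ndarray:
    """Order-statistic feature map: |z| sorted descending per sample."""
    return np.sort(np.abs(Z), axis=1)[:, ::-1]


def _euploid_arm_stats(profiles: pd.DataFrame, arm_map: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    shares = np.column_stack([arm_shares(profiles[c], arm_map) for c in profiles.columns])
    mean = pd.Series(shares.mean(axis=1), index=NON_ACROCENTRIC_ARMS)
    sd = pd.Series(shares.std(axis=1, ddof=1), index=NON_ACROCENTRIC_ARMS)
    sd = sd.clip(lower=1e-12)
    return mean, sd


def build_training_set(
    euploid_profiles: pd.DataFrame,
    arm_map: pd.DataFrame,
    config: AneuploidyConfig,
) -> tuple[pd.DataFrame, np.ndarray, list]:
    """Labelled z-score feature matrix for classifier training.

    Samples are parametric resamples of the fitted euploid reference: counts
    are drawn multinomially at a fresh log-normal depth around the reference
    mean arm shares, so a synthetic sample carries exactly one draw of
    counting noise, like a real profile.  Aneuploid samples first inject
    1..max_events random arm events at a neoplastic fraction drawn
    log-uniformly from ``fraction_range`` (expected-share factor 1 ± nf/2).
    Every row's injected arms and fraction are recorded.  Deterministic
    under ``config.seed``.
    """
    config.validate()
    if euploid_profiles.shape[1] < 50:
        raise ValueError(
            f"need >=50 euploid control profiles, got {euploid_profiles.shape[1]}"
        )
    ref_mean, ref_sd = _euploid_arm_stats(euploid_profiles, arm_map)
    base = ref_mean.to_numpy()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    arms = list(NON_ACROCENTRIC_ARMS)
    lo, hi = config.fraction_range

    rows, labels, events_log = [], [], []
    for i in range(config.n_aneuploid + config.n_euploid):
        aneuploid = i < config.n_aneuploid
        shares = base.copy()
        events: list[tuple[str, str]] = []
        nf = 0.0
        if aneuploid:
            nf = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            n_ev = int(rng.integers(1, config.max_events + 1))
            for a in rng.choice(len(arms), size=n_ev, replace=False):
                kind = "gain" if rng.random() < 0.5 else "loss"
                factor = 1.0 + nf / 2.0 if kind == "gain" else 1.0 - nf / 2.0
                shares[a] *= factor
                events.append((arms[a], kind))
        shares /= shares.sum()
        depth = int(max(np.rint(rng.lognormal(np.log(config.depth_median), config.depth_sigma)), 10_000))
        counts = rng.multinomial(depth, shares)
        z = (counts / depth - ref_mean.to_numpy()) / ref_sd.to_numpy()
        rows.append(z)
        labels.append(int(aneuploid))
        events_log.append({"events": events, "neoplastic_fraction": nf})
    X = pd.DataFrame(rows, columns=arms)
    return X, np.asarray(labels), events_log


class AneuploidyModel:
    """Aneuploidy classifier specification, built from euploid controls.

    Parameters
    ----------
    euploid_profiles : DataFrame
        Locus-count matrix (rows = loci, columns = euploid control samples),
        e.g. peripheral WBC profiles; defines the euploid reference and the
        resampling base of the training set.
    arm_map : DataFrame, optional
        locus_id -> arm assignment over the 39 arms (defaults to the uniform
        synthetic map sized to the profile).
    config : AneuploidyConfig, optional
    """

    def __init__(
        self,
        euploid_profiles: pd.DataFrame,
        arm_map: pd.DataFrame | None = None,
        config: AneuploidyConfig | None = None,
    ) -> None:
        self.config = config if config is not None else AneuploidyConfig()
        self.config.validate()
        self.arm_map = arm_map if arm_map is not None else uniform_arm_map(len(euploid_profiles))
        validate_arm_map(self.arm_map)
        self.euploid_profiles = euploid_profiles

    def fit(self) -> "AneuploidyResults":
        cfg = self.config
        X, y, events = build_training_set(self.euploid_profiles, self.arm_map, cfg)
        if len(set(y)) < 2:
            raise ValueError("training set must contain both classes")
        ref_mean, ref_sd = _euploid_arm_stats(self.euploid_profiles, self.arm_map)

        # class_weight="balanced" in the SVM: the 3150/677 synthetic class
        # ratio is a training artefact and must not leak into the score as a
        # prior.  The Platt calibration additionally up-weights the euploid
        # class (platt_euploid_weight): the assay is specificity-first, so a
        # score of 0.7 must correspond to spike evidence clearly outside the
        # euploid range, at the cost of sensitivity only near the detection
        # limit.
        svc = SVC(kernel=cfg.kernel, C=cfg.svm_c, class_weight="balanced", random_state=cfg.seed)
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=cfg.seed)
        F = _sorted_abs(X.to_numpy())
        oof_decision = cross_val_predict(svc, F, y, cv=cv, method="decision_function")
        svc.fit(F, y)
        platt = LogisticRegression(C=1e6, class_weight={0: cfg.platt_euploid_weight, 1: 1.0})
        platt.fit(oof_decision.reshape(-1, 1), y)

        # |z| cutoff giving the target per-arm call rate on euploid training arms
        euploid_absz = np.abs(X.to_numpy()[y == 0]).ravel()
        arm_call_threshold = float(np.quantile(euploid_absz, 1.0 - cfg.arm_call_euploid_rate))

        gamma = float(svc._gamma) if cfg.kernel == "rbf" else 0.0
        return AneuploidyResults(
            arm_map=self.arm_map,
            ref_mean=ref_mean,
            ref_sd=ref_sd,
            arm_call_threshold=arm_call_threshold,
            score_threshold=cfg.score_threshold,
            kernel=cfg.kernel,
            gamma=gamma,
            support_vectors=svc.support_vectors_.copy(),
            dual_coef=svc.dual_coef_[0].copy(),
            intercept=float(svc.intercept_[0]),
            platt_a=float(platt.coef_[0, 0]),
            platt_b=float(platt.intercept_[0]),
            config=cfg,
            training_events=events,
        )


@dataclass
class AneuploidyResults:
    """A trained aneuploidy classifier with its euploid reference.

    Scoring is self-contained (kernel expansion + Platt sigmoid over the
    stored support vectors), so a saved model reloads bit-stably without
    retraining.
    """

    arm_map: pd.DataFrame
    ref_mean: pd.Series
    ref_sd: pd.Series
    arm_call_threshold: float
    score_threshold: float
    kernel: str
    gamma: float
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    platt_a: float
    platt_b: float
    config: AneuploidyConfig
    training_events: list = field(default_factory=list, repr=False)

    # ------------------------------------------------------------- scoring

    def _decision(self, Z: np.ndarray) -> np.ndarray:
        F = _sorted_abs(Z)
        if self.kernel == "rbf":
            K = rbf_kernel(F, self.support_vectors, gamma=self.gamma)
        else:
            K = F @ self.support_vectors.T
        return K @ self.dual_coef + self.intercept

    def _score_from_z(self, Z: np.ndarray) -> np.ndarray:
        d = self._decision(Z)
        return 1.0 / (1.0 + np.exp(-(self.platt_a * d + self.platt_b)))

    def arm_profile(self, profile: pd.Series) -> ArmZProfile:
        return arm_zscores(profile, self.arm_map, self.ref_mean, self.ref_sd,
                           self.arm_call_threshold)

    def score_sample(self, profile: pd.Series) -> AneuploidyCall:
        """Score one locus-count profile; positive iff score > 0.7 and >=1 arm call."""
        arms = self.arm_profile(profile)
        score = float(self._score_from_z(arms.z.to_numpy()[None, :])[0])
        positive = decision_rule(score, arms.n_called(), self.score_threshold)
        return AneuploidyCall(score=score, arms=arms, positive=positive)

    def score_profiles(self, profiles: pd.DataFrame) -> pd.DataFrame:
        """Score a locus-count matrix (columns = samples)."""
        rows = []
        for col in profiles.columns:
            call = self.score_sample(profiles[col])
            rows.append(
                {
                    "patient_id": col,
                    "aneuploidy_score": call.score,
                    "n_arm_calls": call.arms.n_called(),
                    "aneuploidy_positive": call.positive,
                    "called_arms": ";".join(
                        f"{a}:{c}" for a, c in call.arms.calls.items() if c != "neutral"
                    ),
                }
            )
        return pd.DataFrame(rows).set_index("patient_id")

    # --------------------------------------------------------- diagnostics

    def detection_limit_curve(
        self,
        fractions: Sequence[float],
        n_reps: int = 200,
        seed: int = 0,
        n_events: int = 1,
    ) -> pd.DataFrame:
        """Positive-call rate versus neoplastic fraction.

        For each fraction, simulate ``n_reps`` samples carrying ``n_events``
        single-copy arm gains (arm drawn uniformly per replicate) on the
        euploid reference and report the fraction called positive.
        """
        if len(fractions) == 0:
            raise ValueError("fraction list is empty")
        rng = np.random.default_rng(seed)
        mean = self.ref_mean.to_numpy()
        cfg = self.config
        out = []
        for f in fractions:
            if f < 0:
                raise ValueError(f"neoplastic fraction must be >= 0, got {f}")
            Z = np.empty((n_reps, 39))
            n_called = np.empty(n_reps, dtype=int)
            for r in range(n_reps):
                shares = mean.copy()
                for a in rng.choice(39, size=n_events, replace=False):
                    shares[a] *= 1.0 + f / 2.0
                shares /= shares.sum()
                depth = int(max(np.rint(rng.lognormal(np.log(cfg.depth_median), cfg.depth_sigma)), 10_000))
                counts = rng.multinomial(depth, shares)
                z = (counts / depth - mean) / self.ref_sd.to_numpy()
                Z[r] = z
                n_called[r] = int((np.abs(z) > self.arm_call_threshold).sum())
            scores = self._score_from_z(Z)
            positive = (scores > self.score_threshold) & (n_called >= 1)
            out.append({"neoplastic_fraction": float(f), "detection_rate": float(positive.mean())})
        return pd.DataFrame(out)

    def plot_detection_limit(self, curve: pd.DataFrame | None = None, ax=None, **curve_kwargs):
        """Plot the detection-rate curve on a log-fraction axis.

        ``curve`` defaults to a fresh :meth:`detection_limit_curve` run.
        Returns the matplotlib axes.
        """
        import matplotlib.pyplot as plt

        if curve is None:
            fr = curve_kwargs.pop("fractions", [0.002, 0.005, 0.01, 0.02, 0.05, 0.1])
            curve = self.detection_limit_curve(fr, **curve_kwargs)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve.neoplastic_fraction, curve.detection_rate, marker="o")
        ax.axhline(0.5, ls="--", lw=0.8, color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("neoplastic fraction")
        ax.set_ylabel("positive-call rate")
        ax.set_ylim(-0.02, 1.02)
        return ax

    # --------------------------------------------------------- persistence

    def save(self, path: str | Path) -> None:
        """Write the model to a single versioned JSON file."""
        doc = {
            "format": "uroseek-aneuploidy-model",
            "version": FORMAT_VERSION,
            "config": asdict(self.config),
            "arm_call_threshold": self.arm_call_threshold,
            "score_threshold": self.score_threshold,
            "kernel": self.kernel,
            "gamma": self.gamma,
            "intercept": self.intercept,
            "platt_a": self.platt_a,
            "platt_b": self.platt_b,
            "arms": list(self.ref_mean.index),
            "ref_mean": self.ref_mean.to_list(),
            "ref_sd": self.ref_sd.to_list(),
            "dual_coef": self.dual_coef.tolist(),
            "support_vectors": self.support_vectors.tolist(),
            "arm_map": {
                "locus_id": self.arm_map["locus_id"].to_list(),
                "chrom": self.arm_map["chrom"].to_list(),
                "arm": self.arm_map["arm"].to_list(),
            },
            "n_training_aneuploid": int(self.config.n_aneuploid),
            "n_training_euploid": int(self.config.n_euploid),
        }
        Path(path).write_text(json.dumps(doc))

    def summary(self) -> str:
        cfg = self.config
        return "\n".join(
            [
                "Aneuploidy classifier (SVM over 39 arm z-scores)",
                f"  kernel: {self.kernel} (gamma={self.gamma:.4g}), C={cfg.svm_c}",
                f"  training: {cfg.n_aneuploid} synthetic aneuploid + {cfg.n_euploid} euploid, "
                f"fractions {cfg.fraction_range[0]:g}-{cfg.fraction_range[1]:g}",
                f"  support vectors: {len(self.dual_coef)}",
                f"  arm-call |z| threshold: {self.arm_call_threshold:.3f} "
                f"(target euploid arm call rate {cfg.arm_call_euploid_rate:.1%})",
                f"  positive rule: score > {self.score_threshold} and >=1 arm gain/loss",
            ]
        )

    def __str__(self) -> str:  # pragma: no cover
        return self.summary()


def load_model(path: str | Path) -> AneuploidyResults:
    """Reload a model written by :meth:`AneuploidyResults.save`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "uroseek-aneuploidy-model":
        raise ValueError(f"{path} is not an aneuploidy model file")
    if doc.get("version") != FORMAT_VERSION:
        raise ValueError(f"unsupported model version {doc.get('version')}")
    cfg_kwargs = doc["config"]
    cfg_kwargs["fraction_range"] = tuple(cfg_kwargs["fraction_range"])
    cfg = AneuploidyConfig(**cfg_kwargs)
    arms = doc["arms"]
    arm_map = pd.DataFrame(doc["arm_map"])
    arm_map = arm_map.set_index("locus_id", drop=False)
    return AneuploidyResults(
        arm_map=arm_map,
        ref_mean=pd.Series(doc["ref_mean"], index=arms),
        ref_sd=pd.Series(doc["ref_sd"], index=arms),
        arm_call_threshold=doc["arm_call_threshold"],
        score_threshold=doc["score_threshold"],
        kernel=doc["kernel"],
        gamma=doc["gamma"],
        support_vectors=np.asarray(doc["support_vectors"], dtype=float),
        dual_coef=np.asarray(doc["dual_coef"], dtype=float),
        intercept=doc["intercept"],
        platt_a=doc["platt_a"],
        platt_b=doc["platt_b"],
        config=cfg,
    )
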