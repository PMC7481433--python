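"""End-to-end training/evaluation pipeline on phantom cohorts.

This is the programmatic counterpart of ``ggnav pipeline``: generate a
graded phantom cohort, train the slice classifier on the training split's
tumor slices, train the navigation agent against the frozen classifier,
run patient-level inference on the held-out split, and score both the
model's grades (GG-Pre) and the simulated biopsy grades (GG-NB) against
the reference (GG-RP).

All randomness derives from the single ``seed`` argument through
independent child seeds, so a run is a pure function of its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phantom import PhantomSpec, generate_cohort
from .slice_classifier import TrainConfig, train_classifier, SliceClassifier
from .navigator import DQNConfig, DQNAgent, train_agent, VolumeEnvironment
from .framework import predict_cohort
from . import metrics

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    classifier: SliceClassifier = field(repr=False)
    agent: DQNAgent = field(repr=False)
    predictions: pd.DataFrame = field(repr=False)
    gg_rp: np.ndarray
    gg_nb: np.ndarray
    gg_pre: np.ndarray
    decision_tumor_accuracy: float
    patient_accuracy: float
    classifier_history: pd.DataFrame = field(repr=False)
    test_stacks: list = field(default_factory=list, repr=False)

    def summary(self) -> dict:
        pre = metrics.upgrade_downgrade(list(zip(self.gg_rp, self.gg_pre)))
        nb = metrics.upgrade_downgrade(list(zip(self.gg_rp, self.gg_nb)))
        cm = metrics.confusion_matrix(self.gg_rp, self.gg_pre)
        return {
            "n_test_patients": int(len(self.gg_rp)),
            "patient_accuracy": self.patient_accuracy,
            "decision_tumor_accuracy": self.decision_tumor_accuracy,
            "kappa": metrics.quadratic_kappa(cm),
            "pre_upgrade_rate": pre.upgrade_rate,
            "pre_downgrade_rate": pre.downgrade_rate,
            "nb_upgrade_rate": nb.upgrade_rate,
            "nb_downgrade_rate": nb.downgrade_rate,
            "nb_accuracy": float((self.gg_rp == self.gg_nb).mean()),
        }


def run_pipeline(seed: int = 0, n_train: int = 60, n_val: int = 12,
                 n_test: int = 20, signal_separation: float = 2.0,
                 n_episodes: int = 5000, pool_capacity: int = 2000,
                 image_size: int = 200) -> PipelineResult:
    """Train both networks on phantoms and evaluate on a held-out cohort.

    ``n_val`` patients drive the classifier's early stopping.  The three
    cohorts are generated with independent child seeds of ``seed``.
    Replay updates only start once ``pool_capacity`` transitions have been
    collected, so short demo runs should shrink the pool along with
    ``n_episodes``.
    """
    child = np.random.SeedSequence(seed).spawn(5)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in child]

    def cohort(n, s):
        spec = PhantomSpec(n_patients=n, signal_separation=signal_separation,
                           image_size=image_size, seed=s)
        return generate_cohort(spec)[0]

    train_stacks = cohort(n_train, seeds[0])
    val_stacks = cohort(n_val, seeds[1])
    test_stacks = cohort(n_test, seeds[2])

    clf_cfg = TrainConfig(seed=seeds[3])
    clf, history = train_classifier(train_stacks, val_stacks, clf_cfg)

    dqn_cfg = DQNConfig(seed=seeds[4], n_episodes=n_episodes,
                        pool_capacity=pool_capacity)
    agent = train_agent(train_stacks, clf, dqn_cfg)

    preds = predict_cohort(test_stacks, clf, agent)
    if preds.attrs["n_errors"]:
        raise RuntimeError("prediction failed for some phantoms")
    gg_rp = np.array([s.gg_rp for s in test_stacks])
    gg_nb = np.array([s.gg_nb for s in test_stacks])
    gg_pre = preds["gg_pre"].to_numpy(dtype=int)
    return PipelineResult(
        classifier=clf, agent=agent, predictions=preds,
        gg_rp=gg_rp, gg_nb=gg_nb, gg_pre=gg_pre,
        decision_tumor_accuracy=float(preds["decision_tumor"].mean()),
        patient_accuracy=float((gg_pre == gg_rp).mean()),
        classifier_history=history, test_stacks=test_stacks)
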