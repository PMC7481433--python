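"""Slice-navigation agent (the "action net"): a deep Q-network.

The agent sees the classifier's feature vector for the current slice and
chooses one of seven discrete moves — displacements of −3..+3 slices, with
0 meaning "stay in place" (the stop signal the framework's checkpoint
reacts to).  Two identically shaped value networks are kept: the *current*
net collects experience and is trained by TD regression; the *target* net
supplies the bootstrap targets and receives a hard parameter copy every
``sync_interval`` gradient updates.  Experience is stored in a FIFO replay
pool; no gradient step happens until the pool has filled once.

The per-step reward combines a basic reward y with the classifier's
confidence P at the slice the action lands on:

    r = c * (y + alpha * P),   c = +1 if the landing slice is a tumor slice
                                    and its predicted grade equals the
                                    patient-level grade, else −1

with y = 1 and alpha = 0.5 by default.  The composition is isolated in
:func:`compute_reward` so alternative shapes are one-line swaps.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .nn import MLP, SGDMomentum
from .phantom import VolumeStack
from .slice_classifier import SliceClassifier

__all__ = [
    "Action", "ACTIONS", "Transition", "DQNConfig", "ReplayBuffer",
    "DQNAgent", "compute_reward", "q_values", "select_action", "q_loss",
    "train_agent", "VolumeEnvironment",
]

DISPLACEMENTS = (-3, -2, -1, 0, 1, 2, 3)


@dataclass(frozen=True)
class Action:
    code: int
    displacement: int

    @property
    def is_stay(self) -> bool:
        return self.displacement == 0


ACTIONS = tuple(Action(code=i, displacement=d)
                for i, d in enumerate(DISPLACEMENTS))
STAY = next(a for a in ACTIONS if a.is_stay)


@dataclass
class Transition:
    state: np.ndarray
    action: Action
    reward: float
    next_state: np.ndarray
    terminal: bool

    def __post_init__(self):
        if not np.isfinite(self.reward):
            raise ValueError("reward must be finite")
        if np.shape(self.state) != np.shape(self.next_state):
            raise ValueError("state / next_state length mismatch")


@dataclass(frozen=True)
class DQNConfig:
    input_dim: int = 4320
    hidden_sizes: tuple[int, ...] = (50, 30)
    n_actions: int = 7
    pool_capacity: int = 2000
    sync_interval: int = 100
    sync_unit: str = "updates"      # or "transitions"
    basic_reward: float = 1.0       # y
    reward_rate: float = 0.5        # alpha, weight of the confidence term
    gamma: float = 0.0
    epsilon_start: float = 1.0
    epsilon_end: float = 0.05
    epsilon_anneal_frac: float = 0.7
    batch_size: int = 32
    lr: float = 1e-3
    momentum: float = 0.9
    n_episodes: int = 5000
    max_steps_per_episode: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.sync_interval < 1:
            raise ValueError("sync_interval must be >= 1")
        if self.reward_rate < 0:
            raise ValueError("reward_rate (alpha) must be >= 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if self.sync_unit not in ("updates", "transitions"):
            raise ValueError("sync_unit must be 'updates' or 'transitions'")
        if self.n_actions != len(ACTIONS):
            raise ValueError(f"n_actions must be {len(ACTIONS)}")


def compute_reward(slice_is_tumor: bool, predicted_grade: int,
                   true_grade: int, prob_at_prediction: float,
                   cfg: DQNConfig = DQNConfig()) -> float:
    """r = c*(y + alpha*P); c = +1 iff tumor slice and grades agree."""
    if not 0.0 <= prob_at_prediction <= 1.0:
        raise ValueError(
            f"probability must be in [0, 1], got {prob_at_prediction}")
    consistent = bool(slice_is_tumor) and predicted_grade == true_grade
    c = 1.0 if consistent else -1.0
    return c * (cfg.basic_reward + cfg.reward_rate * prob_at_prediction)


def q_values(net: MLP, state: np.ndarray) -> np.ndarray:
    """Deterministic forward pass; validates the feature dimension."""
    state = np.asarray(state, dtype=np.float64)
    if state.shape[-1] != net.dims[0]:
        raise ValueError(
            f"state length {state.shape[-1]} != input_dim {net.dims[0]}")
    return net.forward(state)


# Tie-break order for equal Q values: smallest |displacement| first, and the
# negative displacement before the positive one at equal magnitude.
_TIE_ORDER = sorted(range(len(ACTIONS)),
                    key=lambda i: (abs(ACTIONS[i].displacement),
                                   ACTIONS[i].displacement))


def select_action(q: np.ndarray, epsilon: float,
                  rng: np.random.Generator) -> Action:
    """Epsilon-greedy over a 7-vector of action values."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must be in [0, 1]")
    q = np.asarray(q, dtype=np.float64).ravel()
    if q.shape != (len(ACTIONS),):
        raise ValueError(f"expected {len(ACTIONS)} action values")
    if epsilon > 0.0 and rng.random() < epsilon:
        return ACTIONS[int(rng.integers(len(ACTIONS)))]
    best = max(q)
    for i in _TIE_ORDER:
        if q[i] == best:
            return ACTIONS[i]
    raise AssertionError("unreachable")


class ReplayBuffer:
    """FIFO experience pool; sampling is uniform with replacement."""

    def __init__(self, capacity: int):
        if capacity < 1:
            raise ValueError("capacity must be >= 1")
        self.capacity = capacity
        self._items: deque[Transition] = deque(maxlen=capacity)

    def push(self, t: Transition) -> None:
        self._items.append(t)

    def __len__(self) -> int:
        return len(self._items)

    @property
    def is_full(self) -> bool:
        return len(self._items) >= self.capacity

    def sample(self, batch_size: int,
               rng: np.random.Generator) -> list[Transition]:
        idx = rng.integers(len(self._items), size=batch_size)
        return [self._items[i] for i in idx]


def q_loss(batch: list[Transition], current_net: MLP, target_net: MLP,
           gamma: float) -> float:
    """Mean squared TD error over a batch.

    Targets use the *target* net: r + gamma * max_a' Q_target(s', a') for
    non-terminal transitions, r alone for terminal ones.  The target term
    is a constant w.r.t. the current net's parameters (no gradient flows
    into the target net).
    """
    if not batch:
        raise ValueError("empty batch")
    s = np.stack([t.state for t in batch])
    s2 = np.stack([t.next_state for t in batch])
    a = np.array([t.action.code for t in batch])
    r = np.array([t.reward for t in batch])
    term = np.array([t.terminal for t in batch])
    q_next = q_values(target_net, s2).max(axis=1)
    target = r + gamma * q_next * ~term
    q_sa = q_values(current_net, s)[np.arange(len(batch)), a]
    return float(np.mean((q_sa - target) ** 2))


class VolumeEnvironment:
    """Cohort of stacks with classifier readouts cached once.

    The classifier is frozen during agent training, so per-slice features,
    probabilities and predicted grades are computed a single time.
    """

    def __init__(self, stacks: list[VolumeStack],
                 classifier: SliceClassifier):
        offset = 0 if classifier.cfg.n_classes == 6 else 1
        self.patients = []
        for stack in stacks:
            feats = classifier.features_for_stack(stack)
            probs = classifier.predict_features(feats)
            self.patients.append({
                "features": feats,
                "probs": probs,
                "pred_grade": probs.argmax(axis=1) + offset,
                "pred_prob": probs.max(axis=1),
                "tumor_flags": stack.tumor_flags,
                "grade": stack.gg_rp,
                "n_slices": stack.n_slices,
            })
        self.feature_dim = self.patients[0]["features"].shape[1]
        # Q-net input scaling: center per feature, one global scale
        # (per-feature whitening would blow up silent conv features)
        allf = np.concatenate([p["features"] for p in self.patients])
        self.mu = allf.mean(axis=0)
        self.sd = np.asarray(max(float((allf - self.mu).std()), 1e-8))

    def state(self, patient: int, index: int) -> np.ndarray:
        p = self.patients[patient]
        return (p["features"][index] - self.mu) / self.sd


@dataclass
class DQNAgent:
    """Current/target Q-networks plus the input whitening constants."""

    current: MLP
    target: MLP
    mu: np.ndarray
    sd: np.ndarray
    cfg: DQNConfig
    log: pd.DataFrame | None = field(default=None, repr=False)

    def q_for_features(self, features: np.ndarray,
                       use_target: bool = True) -> np.ndarray:
        net = self.target if use_target else self.current
        return q_values(net, (features - self.mu) / self.sd)

    def act(self, features: np.ndarray, use_target: bool = True) -> Action:
        """Greedy action (epsilon = 0); inference uses the target net."""
        rng = np.random.default_rng(0)   # unused at epsilon=0
        return select_action(self.q_for_features(features, use_target),
                             0.0, rng)

    def state_dict(self) -> dict:
        return {"current": self.current.state_dict(),
                "target": self.target.state_dict(),
                "mu": self.mu, "sd": self.sd}

    @classmethod
    def from_state_dict(cls, state: dict,
                        cfg: DQNConfig = DQNConfig()) -> "DQNAgent":
        return cls(current=MLP.from_state_dict(state["current"]),
                   target=MLP.from_state_dict(state["target"]),
                   mu=np.asarray(state["mu"]), sd=np.asarray(state["sd"]),
                   cfg=cfg)


def _epsilon(episode: int, cfg: DQNConfig) -> float:
    horizon = max(1, int(cfg.epsilon_anneal_frac * cfg.n_episodes))
    frac = min(1.0, episode / horizon)
    return cfg.epsilon_start + frac * (cfg.epsilon_end - cfg.epsilon_start)


def _update(net: MLP, opt: SGDMomentum, batch: list[Transition],
            target_net: MLP, gamma: float) -> float:
    s = np.stack([t.state for t in batch])
    s2 = np.stack([t.next_state for t in batch])
    a = np.array([t.action.code for t in batch])
    r = np.array([t.reward for t in batch])
    term = np.array([t.terminal for t in batch])
    q_next = q_values(target_net, s2).max(axis=1)
    target = r + gamma * q_next * ~term
    q, acts = net.forward(s, return_activations=True)
    idx = np.arange(len(batch))
    err = q[idx, a] - target
    grad = np.zeros_like(q)
    grad[idx, a] = 2.0 * err / len(batch)
    opt.step(*net.backward(acts, grad))
    return float(np.mean(err ** 2))


def train_agent(stacks: list[VolumeStack], classifier: SliceClassifier,
                cfg: DQNConfig = DQNConfig(),
                env: VolumeEnvironment | None = None) -> DQNAgent:
    """Train the navigation agent on a cohort with a frozen classifier.

    Episodes start at a uniformly random slice (environment augmentation);
    each runs at most ``max_steps_per_episode`` steps and ends early on a
    stay-in-place action.  Replay updates begin only once the pool has
    overflowed; the target net is hard-synced every ``sync_interval``
    gradient updates (or stored transitions when ``sync_unit`` is
    "transitions").  The returned agent's ``log`` records per-episode
    return, epsilon, update/sync counters and boundary clips, plus the
    transition count at the first update as instrumentation.
    """
    env = env or VolumeEnvironment(stacks, classifier)
    if env.feature_dim != cfg.input_dim:
        raise ValueError(
            f"classifier feature_dim {env.feature_dim} != agent input_dim "
            f"{cfg.input_dim}")
    rng = np.random.default_rng(cfg.seed)
    dims = [cfg.input_dim, *cfg.hidden_sizes, cfg.n_actions]
    current = MLP(dims, rng=rng)
    target = MLP(dims, init="zeros")
    target.copy_parameters_from(current)
    opt = SGDMomentum(current, lr=cfg.lr, momentum=cfg.momentum)
    pool = ReplayBuffer(cfg.pool_capacity)

    n_updates = n_transitions = n_syncs = n_clips = 0
    first_update_at: int | None = None
    records = []
    for episode in range(cfg.n_episodes):
        pi = int(rng.integers(len(env.patients)))
        patient = env.patients[pi]
        n = patient["n_slices"]
        index = int(rng.integers(n))
        eps = _epsilon(episode, cfg)
        ep_return = 0.0
        for step in range(cfg.max_steps_per_episode):
            state = env.state(pi, index)
            action = select_action(q_values(current, state), eps, rng)
            proposed = index + action.displacement
            landed = int(np.clip(proposed, 0, n - 1))
            if landed != proposed:
                n_clips += 1
            reward = compute_reward(
                bool(patient["tumor_flags"][landed]),
                int(patient["pred_grade"][landed]),
                int(patient["grade"]),
                float(patient["pred_prob"][landed]), cfg)
            terminal = action.is_stay or step == cfg.max_steps_per_episode - 1
            pool.push(Transition(state=state, action=action, reward=reward,
                                 next_state=env.state(pi, landed),
                                 terminal=terminal))
            n_transitions += 1
            ep_return += reward
            index = landed
            if pool.is_full:
                if first_update_at is None:
                    first_update_at = n_transitions
                batch = pool.sample(cfg.batch_size, rng)
                _update(current, opt, batch, target, cfg.gamma)
                n_updates += 1
                counter = (n_updates if cfg.sync_unit == "updates"
                           else n_transitions)
                if counter % cfg.sync_interval == 0:
                    target.copy_parameters_from(current)
                    n_syncs += 1
            if terminal:
                break
        records.append({"episode": episode, "return": ep_return,
                        "epsilon": eps, "n_updates": n_updates,
                        "n_syncs": n_syncs, "n_clips": n_clips})
    log = pd.DataFrame(records)
    log.attrs["first_update_at_transition"] = first_update_at
    log.attrs["pool_capacity"] = cfg.pool_capacity
    agent = DQNAgent(current=current, target=target, mu=env.mu, sd=env.sd,
                     cfg=cfg, log=log)
    return agent
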