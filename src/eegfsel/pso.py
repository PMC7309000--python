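"""Wrapper feature selection by particle swarm optimization with a
multi-stage linearly-decreasing inertia weight (MLDW), plus a Relief filter
baseline.

Each particle is a real-valued vector over the feature columns; positions
above a threshold theta (default 0.8) decode to "feature selected".  Fitness
is the stratified inner-cross-validated error rate of a linear SVM on the
masked columns, so the selector directly optimizes downstream recognition
error.  The inertia weight w in the velocity update

    V <- w*V + C1*R1*(pbest - X) + C2*R2*(gbest - X)

is scheduled per iteration: constant, linearly decreasing from ``ws`` to
``we`` (LDW), or in three stages — linear descent to a plateau ``wm`` over
``[0, t1]``, constant on ``(t1, t2]``, then linear descent to ``we`` on
``(t2, tmax]`` (MLDW).  Named strategies ``w1``..``w6`` are the six standard
(wm, t1, t2) combinations; ``w0`` is the LDW baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "InertiaSchedule",
    "STRATEGIES",
    "inertia_weight",
    "PSOConfig",
    "Particle",
    "SelectionResult",
    "decode_mask",
    "update_velocity",
    "update_position",
    "FitnessEvaluator",
    "select_features",
    "relief_select",
]

#: Multi-stage parameters (wm, t1, t2) of the six named MLDW strategies.
STRATEGIES: dict[str, tuple[float, int, int]] = {
    "w1": (0.8, 10, 40),
    "w2": (0.8, 20, 30),
    "w3": (0.65, 10, 40),
    "w4": (0.65, 20, 30),
    "w5": (0.5, 10, 40),
    "w6": (0.5, 20, 30),
}


@dataclass(frozen=True)
class InertiaSchedule:
    """Inertia-weight law evaluated per iteration.

    ``kind`` is one of ``constant`` (always ``ws``), ``ldw`` (linear from
    ``ws`` at t=0 to ``we`` at t=tmax) or ``mldw`` (three-stage descent with
    plateau ``wm`` between iterations ``t1`` and ``t2``).  The MLDW law is
    continuous at both stage boundaries.
    """

    kind: str = "mldw"
    ws: float = 0.9
    we: float = 0.4
    wm: float | None = None
    t1: int | None = None
    t2: int | None = None
    tmax: int = 50

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "ldw", "mldw"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "mldw":
            if self.wm is None or self.t1 is None or self.t2 is None:
                raise ValueError("mldw schedule needs wm, t1, t2")
            if not 0 <= self.we <= self.wm <= self.ws <= 1:
                raise ValueError("need 0 <= we <= wm <= ws <= 1")
            if not 0 < self.t1 < self.t2 < self.tmax:
                raise ValueError("need 0 < t1 < t2 < tmax")
        elif not 0 <= self.we <= self.ws <= 1:
            raise ValueError("need 0 <= we <= ws <= 1")

    @classmethod
    def strategy(cls, name: str, tmax: int = 50, ws: float = 0.9, we: float = 0.4):
        """Named strategies: ``w0`` = LDW baseline, ``w1``..``w6`` = MLDW."""
        if name == "w0":
            return cls(kind="ldw", ws=ws, we=we, tmax=tmax)
        if name == "constant":
            return cls(kind="constant", ws=ws, we=we, tmax=tmax)
        try:
            wm, t1, t2 = STRATEGIES[name]
        except KeyError:
            raise ValueError(
                f"unknown strategy {name!r}; expected w0..w6 or 'constant'"
            ) from None
        return cls(kind="mldw", ws=ws, we=we, wm=wm, t1=t1, t2=t2, tmax=tmax)

    def weight(self, t: int | float) -> float:
        return inertia_weight(self, t)

    def __call__(self, t: int | float) -> float:
        return inertia_weight(self, t)


def inertia_weight(schedule: InertiaSchedule, t: int | float) -> float:
    """Evaluate the schedule at iteration ``t`` (0 <= t <= tmax)."""
    if not 0 <= t <= schedule.tmax:
        raise ValueError(f"iteration {t} outside [0, {schedule.tmax}]")
    if schedule.kind == "constant":
        return schedule.ws
    if schedule.kind == "ldw":
        return (schedule.ws - schedule.we) * (schedule.tmax - t) / schedule.tmax + schedule.we
    ws, we, wm = schedule.ws, schedule.we, schedule.wm
    t1, t2, tmax = schedule.t1, schedule.t2, schedule.tmax
    if t <= t1:
        return (ws - wm) * (t1 - t) / t1 + wm
    if t <= t2:
        return wm
    return (wm - we) * (tmax - t) / (tmax - t2) + we


@dataclass
class Particle:
    """Swarm member: real position/velocity plus personal-best memory."""

    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = np.inf


@dataclass
class PSOConfig:
    """Swarm hyper-parameters.

    ``theta`` is the selection threshold on position values; ``c1``/``c2``
    the cognitive and social acceleration coefficients.  ``inner_folds`` and
    ``svm_c`` parameterize the wrapped fitness classifier.
    """

    n_particles: int = 20
    c1: float = 2.0
    c2: float = 2.0
    theta: float = 0.8
    tmax: int = 50
    schedule: InertiaSchedule | str = "w6"
    velocity_clamp: float = 0.4
    init_low: float = 0.0
    init_high: float = 1.0
    init_velocity: float = 0.1
    seed: int = 0
    inner_folds: int = 3
    svm_c: float = 1.0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("need at least 2 particles")
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("acceleration coefficients must be positive")
        if isinstance(self.schedule, str):
            self.schedule = InertiaSchedule.strategy(self.schedule, tmax=self.tmax)
        elif self.schedule.tmax != self.tmax:
            self.schedule = replace(self.schedule, tmax=self.tmax)


@dataclass
class SelectionResult:
    """Outcome of a selection run."""

    mask: np.ndarray                  # boolean, length F
    gbest_position: np.ndarray
    gbest_fitness: float
    history: list[dict]               # per iteration: t, w, gbest_fitness, n_selected
    gbest_snapshots: dict[int, np.ndarray] = field(default_factory=dict)
    positions: np.ndarray | None = None    # final swarm positions (K x F)
    velocities: np.ndarray | None = None   # final swarm velocities (K x F)

    @property
    def n_selected(self) -> int:
        return int(self.mask.sum())


def decode_mask(position: np.ndarray, theta: float) -> np.ndarray:
    """Positions strictly above ``theta`` are selected; an all-below swarm
    degenerates to the single best-scoring feature."""
    if theta < 0:
        raise ValueError("theta must be non-negative")
    mask = np.asarray(position) > theta
    if not mask.any():
        mask = np.zeros_like(mask)
        mask[int(np.argmax(position))] = True
    return mask


def update_velocity(
    particle: Particle,
    gbest_position: np.ndarray,
    w: float,
    c1: float,
    c2: float,
    rng: np.random.Generator,
    velocity_clamp: float = 0.4,
) -> np.ndarray:
    """Velocity update with fresh uniform(0,1) draws per component, clamped
    to ``+/- velocity_clamp``."""
    r1 = rng.uniform(size=particle.position.size)
    r2 = rng.uniform(size=particle.position.size)
    v = (
        w * particle.velocity
        + c1 * r1 * (particle.pbest_position - particle.position)
        + c2 * r2 * (gbest_position - particle.position)
    )
    return np.clip(v, -velocity_clamp, velocity_clamp)


def update_position(particle: Particle) -> np.ndarray:
    """Position update: X <- X + V (positions are not clamped)."""
    return particle.position + particle.velocity


class FitnessEvaluator:
    """Error rate of a linear SVM under stratified inner cross-validation.

    The fold assignment is fixed once from the seed, so fitness is a
    deterministic function of the mask; results are cached by mask.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        inner_folds: int = 3,
        svm_c: float = 1.0,
        seed: int = 0,
    ) -> None:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and labels must have matching rows")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("fitness needs at least two classes")
        n_folds = min(inner_folds, int(counts.min()))
        if n_folds < 2:
            raise ValueError("need at least 2 trials per class for inner CV")
        self.X, self.y = X, y
        self.svm_c = svm_c
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        self._splits = [
            (tr.copy(), te.copy()) for tr, te in skf.split(X, y)
        ]
        self._cache: dict[bytes, float] = {}
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        mask = np.asarray(mask, dtype=bool)
        if not mask.any():
            raise ValueError("mask selects no features")
        key = np.packbits(mask).tobytes()
        if key in self._cache:
            return self._cache[key]
        Xm = self.X[:, mask]
        errors = 0
        total = 0
        for tr, te in self._splits:
            clf = SVC(kernel="linear", C=self.svm_c)
            clf.fit(Xm[tr], self.y[tr])
            pred = clf.predict(Xm[te])
            errors += int((pred != self.y[te]).sum())
            total += te.size
        rate = errors / total
        self._cache[key] = rate
        self.n_evaluations += 1
        return rate


def select_features(
    features,
    labels: np.ndarray,
    config: PSOConfig | None = None,
    fitness=None,
    snapshot_at: tuple[int, ...] = (),
) -> SelectionResult:
    """Run the swarm and return the global-best feature mask.

    The random stream (seeded from ``config.seed``) is consumed in a fixed
    order — initial positions, initial velocities, then per iteration and
    particle the R1 and R2 vectors — so runs are bitwise reproducible.
    Iteration ``t`` evaluates the current swarm, updates personal/global
    bests (strict improvement only; ties keep the incumbent), computes the
    scheduled inertia weight and moves the particles.

    ``snapshot_at`` records copies of the global-best position after the
    listed iterations (e.g. ``(10, 30, 50)``) for budget comparisons.
    ``fitness`` may override the default linear-SVM inner-CV evaluator.
    """
    config = config or PSOConfig()
    X = features.values if hasattr(features, "values") else np.asarray(features)
    y = np.asarray(labels)
    if fitness is None:
        fitness = FitnessEvaluator(
            X, y, config.inner_folds, config.svm_c, seed=config.seed
        )
    n_features = X.shape[1]
    rng = np.random.default_rng(config.seed)
    positions = rng.uniform(config.init_low, config.init_high, (config.n_particles, n_features))
    velocities = rng.uniform(
        -config.init_velocity, config.init_velocity, (config.n_particles, n_features)
    )
    swarm = [
        Particle(positions[i], velocities[i], positions[i].copy())
        for i in range(config.n_particles)
    ]
    gbest_position = swarm[0].position.copy()
    gbest_fitness = np.inf
    history: list[dict] = []
    snapshots: dict[int, np.ndarray] = {}

    for t in range(1, config.tmax + 1):
        for p in swarm:
            fit = fitness(decode_mask(p.position, config.theta))
            if fit < p.pbest_fitness:
                p.pbest_fitness = fit
                p.pbest_position = p.position.copy()
            if fit < gbest_fitness:
                gbest_fitness = fit
                gbest_position = p.position.copy()
        w = inertia_weight(config.schedule, t)
        for p in swarm:
            p.velocity = update_velocity(
                p, gbest_position, w, config.c1, config.c2, rng, config.velocity_clamp
            )
            p.position = update_position(p)
        gmask = decode_mask(gbest_position, config.theta)
        history.append(
            {
                "t": t,
                "w": w,
                "gbest_fitness": gbest_fitness,
                "n_selected": int(gmask.sum()),
            }
        )
        if t in snapshot_at:
            snapshots[t] = gbest_position.copy()

    return SelectionResult(
        mask=decode_mask(gbest_position, config.theta),
        gbest_position=gbest_position,
        gbest_fitness=gbest_fitness,
        history=history,
        gbest_snapshots=snapshots,
        positions=np.stack([p.position for p in swarm]),
        velocities=np.stack([p.velocity for p in swarm]),
    )


# --- Relief baseline ------------------------------------------------------


def relief_weights(features, labels: np.ndarray) -> np.ndarray:
    """Classic Relief weights over all instances.

    Features are range-normalized; for every instance the nearest same-class
    neighbour (hit) and nearest other-class neighbour (miss) under the
    Euclidean metric contribute ``|x - miss| - |x - hit|`` per feature.  For
    more than two classes the nearest miss is taken over all other classes.
    """
    X = features.values if hasattr(features, "values") else np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("Relief needs >=2 classes with >=2 instances each")
    span = X.max(axis=0) - X.min(axis=0)
    span[span == 0] = 1.0
    Z = (X - X.min(axis=0)) / span
    n = Z.shape[0]
    d2 = ((Z[:, None, :] - Z[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d2, np.inf)
    weights = np.zeros(Z.shape[1])
    same = y[:, None] == y[None, :]
    for i in range(n):
        hits = np.where(same[i])[0]
        misses = np.where(~same[i])[0]
        hit = hits[np.argmin(d2[i, hits])]
        miss = misses[np.argmin(d2[i, misses])]
        weights += np.abs(Z[i] - Z[miss]) - np.abs(Z[i] - Z[hit])
    return weights / n


def relief_select(
    features, labels: np.ndarray, keep_fraction: float = 0.5
) -> np.ndarray:
    """Keep the top ``floor(keep_fraction * F)`` features by Relief weight.

    Ties are broken by ascending feature index, so the mask is deterministic.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    w = relief_weights(features, labels)
    n_keep = max(1, int(np.floor(keep_fraction * w.size)))
    # stable sort on -w keeps lower indices first among ties
    order = np.argsort(-w, kind="stable")
    mask = np.zeros(w.size, dtype=bool)
    mask[order[:n_keep]] = True
    return mask
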