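"""Firefly-algorithm feature selection with learning-automata-adapted gamma.

Wrapper feature selection: each swarm member is a continuous weight
vector theta in [0,1]^D; features with weight above 0.5 are active, and
the member's fitness is 1/CAv, the reciprocal of the validation
accuracy of an SRDA classifier trained on the active features (a
minimization problem, fitness >= 1).

The firefly algorithm moves each member toward the current brightest
(best-fitness) member with attractiveness

    beta(r) = beta_min + (beta0 - beta_min) * exp(-gamma * r^2)

plus a uniform random step. The absorption coefficient gamma controls
how sharply attraction decays with distance: small gamma -> strong
pull toward the best (exploitation), large gamma -> weak pull (local
exploration). Rather than fixing gamma, each member carries a learning
automaton: a row of a row-stochastic transition matrix C over 20
quantized gamma levels in (0, 1]. Every generation the member draws its
gamma by roulette from its row, and the row is reinforced with the
classical linear reward-penalty (L_RP) scheme according to whether the
member's fitness improved on its own previous-generation value:

    reward:  C_j <- C_j + a(1 - C_j),        C_x <- (1-a) C_x   (x != j)
    punish:  C_j <- (1-b) C_j,               C_x <- b/(e-1) + (1-b) C_x

with a = b = 0.1 and e = 20 actions. The automaton thus learns, per
member, which absorption regime pays off, countering the plain firefly
algorithm's tendency to collapse into a local optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .srda import evaluate, fit_srda, predict_srda

__all__ = [
    "FaLaConfig",
    "FireflySwarm",
    "TransitionMatrix",
    "SelectionResult",
    "init_population",
    "activate_features",
    "evaluate_fitness",
    "select_gamma",
    "update_transition_row",
    "attractiveness",
    "move_firefly",
    "stratified_split",
    "run_fa_la",
]

#: Fitness assigned when validation accuracy is zero (1/CAv undefined).
ZERO_ACCURACY_PENALTY = 1e6


@dataclass
class FaLaConfig:
    """Knobs of the selector.

    pop_size : number of fireflies (50 in the reference configuration).
    generations : FA iterations (genmax).
    a, b : reward / penalty feedback factors of the L_RP automaton.
    n_levels : quantized gamma actions, the values {1/e, 2/e, ..., 1}.
    beta_min, beta0 : attractiveness bounds; alpha : random-step size.
    val_fraction : stratified share of the data held out inside the
        selection loop to score candidate subsets (0.25 mirrors a
        75/25 train/validation protocol).
    srda_alpha : ridge coefficient of the wrapped classifier.
    all_pairs : classical all-pairs firefly sweep instead of the
        move-toward-global-best rule.
    fixed_gamma : disable the learning automaton and use this constant
        absorption coefficient throughout (the plain-FA ablation);
        ``None`` enables LA adaptation.
    """

    pop_size: int = 50
    generations: int = 50
    a: float = 0.1
    b: float = 0.1
    n_levels: int = 20
    beta_min: float = 0.3
    beta0: float = 1.0
    alpha: float = 1.0
    val_fraction: float = 0.25
    srda_alpha: float = 0.01
    all_pairs: bool = False
    fixed_gamma: float | None = None
    seed: int = 0


@dataclass
class FireflySwarm:
    """Population positions and their latest fitness values."""

    positions: np.ndarray  # (pop_size, D) in [0,1]
    fitness: np.ndarray  # (pop_size,)
    generation: int = 0


@dataclass
class TransitionMatrix:
    """Per-member learning automata over quantized gamma levels."""

    c: np.ndarray  # (pop_size, n_levels), row-stochastic
    levels: np.ndarray  # the gamma values in (0, 1]
    a: float = 0.1
    b: float = 0.1

    @property
    def e(self) -> int:
        return self.c.shape[1]

    @classmethod
    def uniform(
        cls, pop_size: int, n_levels: int = 20, a: float = 0.1, b: float = 0.1
    ) -> "TransitionMatrix":
        c = np.full((pop_size, n_levels), 1.0 / n_levels)
        levels = np.arange(1, n_levels + 1) / n_levels
        return cls(c, levels, a, b)


@dataclass
class SelectionResult:
    """Outcome of a selection run."""

    mask: np.ndarray  # boolean, length D
    best_fitness_history: list[float]
    best_member: np.ndarray
    gamma_log: list[np.ndarray] = field(default_factory=list)
    transition: TransitionMatrix | None = None

    @property
    def selected_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    @property
    def best_accuracy(self) -> float:
        """Validation accuracy of the best member (CAv = 1/fitness)."""
        return 1.0 / self.best_fitness_history[-1]


def init_population(pop_size: int, d: int, seed: int | np.random.Generator) -> FireflySwarm:
    """Uniform [0,1] initial positions, reproducible from the seed."""
    if d < 1 or pop_size < 1:
        raise ValueError("pop_size and D must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = rng.uniform(0.0, 1.0, size=(pop_size, d))
    return FireflySwarm(pos, np.full(pop_size, np.inf))


def activate_features(theta: np.ndarray) -> np.ndarray:
    """Binary mask: feature j active iff w_j > 0.5 (strict).

    A member whose weights all sit at or below 0.5 would select nothing,
    leaving its fitness undefined; in that case the single largest
    weight is activated instead.
    """
    theta = np.asarray(theta, dtype=float)
    mask = theta > 0.5
    if not mask.any():
        mask = np.zeros(theta.shape, dtype=bool)
        mask[np.argmax(theta)] = True
    return mask


def stratified_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Index split keeping per-class proportions; at least one validation
    trial per class."""
    y = np.asarray(labels).ravel()
    train_idx, val_idx = [], []
    for k in np.unique(y):
        idx = np.flatnonzero(y == k)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(val_fraction * idx.size)))
        if n_val >= idx.size:
            raise ValueError(f"class {k} too small to split off validation trials")
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


def evaluate_fitness(
    theta: np.ndarray,
    train_x: np.ndarray,
    train_y: np.ndarray,
    val_x: np.ndarray,
    val_y: np.ndarray,
    srda_alpha: float = 0.01,
) -> float:
    """Fitness(i) = 1 / CAv of SRDA on the member's active features.

    The classifier is trained on the training partition restricted to
    the activated columns and scored on the validation partition; zero
    accuracy maps to a large finite penalty so the minimization stays
    well defined.
    """
    mask = activate_features(theta)
    missing = set(np.unique(val_y)) - set(np.unique(train_y))
    if missing:
        raise ValueError(
            f"degenerate split: classes {sorted(missing)} absent from training data"
        )
    model = fit_srda(train_x[:, mask], train_y, srda_alpha)
    pred = predict_srda(model, val_x[:, mask])
    cav = float(np.mean(pred == np.asarray(val_y).ravel()))
    if cav == 0.0:
        return ZERO_ACCURACY_PENALTY
    return 1.0 / cav


def select_gamma(
    row: np.ndarray, rng: np.random.Generator, levels: np.ndarray | None = None
) -> tuple[int, float]:
    """Roulette draw of a gamma level from one automaton row.

    Draws r uniform in (0, 1] and returns the first index j whose
    cumulative probability reaches r, plus the corresponding gamma.
    """
    row = np.asarray(row, dtype=float)
    if abs(row.sum() - 1.0) > 1e-9 or np.any(row < 0):
        raise ValueError("automaton row must be a probability vector")
    if levels is None:
        levels = np.arange(1, row.size + 1) / row.size
    r = 1.0 - rng.uniform(0.0, 1.0)  # uniform on (0, 1]
    cum = np.cumsum(row)
    cum[-1] = 1.0  # guard against rounding
    j = int(np.searchsorted(cum, r, side="left"))
    return j, float(levels[j])


def update_transition_row(
    row: np.ndarray, j: int, improved: bool, a: float = 0.1, b: float = 0.1
) -> np.ndarray:
    """One linear reward-penalty (L_RP) update of an automaton row.

    Reward (the chosen action improved fitness) concentrates mass on j;
    penalty bleeds mass from j to the other e-1 actions. Both branches
    preserve row-stochasticity exactly.
    """
    row = np.asarray(row, dtype=float)
    e = row.size
    out = row.copy()
    if improved:
        out *= 1.0 - a
        out[j] = row[j] + a * (1.0 - row[j])
    else:
        out = b / (e - 1) + (1.0 - b) * row
        out[j] = (1.0 - b) * row[j]
    return out


def attractiveness(
    r: float, gamma: float, beta_min: float = 0.3, beta0: float = 1.0
) -> float:
    """Bounded firefly attractiveness beta_min + (beta0-beta_min)e^{-gamma r^2}."""
    if r < 0 or gamma <= 0:
        raise ValueError("distance must be >= 0 and gamma > 0")
    return beta_min + (beta0 - beta_min) * float(np.exp(-gamma * r * r))


def move_firefly(
    theta_i: np.ndarray,
    theta_target: np.ndarray,
    gamma_i: float,
    alpha: float,
    rng: np.random.Generator,
    beta_min: float = 0.3,
    beta0: float = 1.0,
) -> np.ndarray:
    """Move one firefly toward the target and clamp to [0,1]^D.

    The distance entering the attractiveness is the Euclidean norm
    normalized by sqrt(D), so the (0,1] gamma quantization behaves the
    same at any dimensionality.
    """
    theta_i = np.asarray(theta_i, dtype=float)
    theta_target = np.asarray(theta_target, dtype=float)
    d = theta_i.size
    r = float(np.linalg.norm(theta_target - theta_i)) / np.sqrt(d)
    beta = attractiveness(r, gamma_i, beta_min, beta0)
    step = alpha * (rng.uniform(0.0, 1.0, size=d) - 0.5)
    return np.clip(theta_i + beta * (theta_target - theta_i) + step, 0.0, 1.0)


def run_fa_la(
    features: np.ndarray,
    labels: np.ndarray,
    config: FaLaConfig | None = None,
) -> SelectionResult:
    """Full FA-LA wrapper selection on a feature matrix.

    The data are split once (stratified, held fixed for the whole run)
    into an inner training and validation partition. Generation 0
    evaluates the random initial population to seed each member's
    fitness baseline. Every subsequent generation, per member: a gamma
    is drawn from the member's automaton row, the member moves toward
    the current best (the best member itself is kept in place —
    elitism), its fitness is re-evaluated, and the row is rewarded if
    the fitness improved on the member's previous value, else punished.
    The returned mask is the best-ever member's activation. The whole
    run is a pure function of (features, labels, config).
    """
    cfg = config or FaLaConfig()
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels).ravel()
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("features must be trials x D with D >= 2")
    if np.unique(y).size < 2:
        raise ValueError("need at least 2 classes")
    rng = np.random.default_rng(cfg.seed)
    tr_idx, va_idx = stratified_split(y, cfg.val_fraction, rng)
    tr_x, tr_y = x[tr_idx], y[tr_idx]
    va_x, va_y = x[va_idx], y[va_idx]

    swarm = init_population(cfg.pop_size, x.shape[1], rng)
    automata = TransitionMatrix.uniform(cfg.pop_size, cfg.n_levels, cfg.a, cfg.b)

    def fit_of(theta: np.ndarray) -> float:
        return evaluate_fitness(theta, tr_x, tr_y, va_x, va_y, cfg.srda_alpha)

    swarm.fitness = np.array([fit_of(t) for t in swarm.positions])
    best_i = int(np.argmin(swarm.fitness))
    best_pos = swarm.positions[best_i].copy()
    best_fit = float(swarm.fitness[best_i])
    history = [best_fit]
    gamma_log: list[np.ndarray] = []

    for _ in range(cfg.generations):
        swarm.generation += 1
        gammas = np.empty(cfg.pop_size)
        chosen = np.empty(cfg.pop_size, dtype=int)
        for i in range(cfg.pop_size):
            if cfg.fixed_gamma is not None:
                chosen[i], gammas[i] = -1, cfg.fixed_gamma
            else:
                chosen[i], gammas[i] = select_gamma(automata.c[i], rng, automata.levels)
        gamma_log.append(gammas.copy())

        cur_best = int(np.argmin(swarm.fitness))
        new_pos = swarm.positions.copy()
        for i in range(cfg.pop_size):
            if i == cur_best:
                continue  # elitism: the brightest firefly does not move
            if cfg.all_pairs:
                pos = swarm.positions[i]
                for jj in range(cfg.pop_size):
                    if swarm.fitness[jj] < swarm.fitness[i]:
                        pos = move_firefly(
                            pos, swarm.positions[jj], gammas[i], cfg.alpha,
                            rng, cfg.beta_min, cfg.beta0,
                        )
                new_pos[i] = pos
            else:
                new_pos[i] = move_firefly(
                    swarm.positions[i], swarm.positions[cur_best], gammas[i],
                    cfg.alpha, rng, cfg.beta_min, cfg.beta0,
                )
        swarm.positions = new_pos

        for i in range(cfg.pop_size):
            new_fit = fit_of(swarm.positions[i]) if i != cur_best else swarm.fitness[i]
            improved = new_fit < swarm.fitness[i]
            if cfg.fixed_gamma is None:
                automata.c[i] = update_transition_row(
                    automata.c[i], int(chosen[i]), improved, cfg.a, cfg.b
                )
            swarm.fitness[i] = new_fit

        gen_best = int(np.argmin(swarm.fitness))
        if swarm.fitness[gen_best] < best_fit:
            best_fit = float(swarm.fitness[gen_best])
            best_pos = swarm.positions[gen_best].copy()
        history.append(best_fit)

    return SelectionResult(
        activate_features(best_pos), history, best_pos, gamma_log, automata
    )
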