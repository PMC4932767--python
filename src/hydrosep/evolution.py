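"""Random hydrophobicity scales and their in-silico evolutionary refinement.

Random scales draw each amino-acid value uniformly from the global
[min, max] interval of an input scale corpus.  Evolution is a single-parent
hill climb with elitism: each round perturbs exactly one amino acid of the
current best scale per child (uniform draw from a signed magnitude
interval) and keeps the best of children plus parent.  The default schedule
is six rounds: two broad rounds over all 20 amino acids (positive then
negative perturbations, 50 children per amino acid each), three focused
rounds on the amino acids found most influential (E, Y up; A, H, F, L down;
then E up / A, H down with doubled intervals; then E alone), and a final
mixed-sign round of 25 + 25 children per amino acid.

Fitness of a scale is the mean separation score over all unordered pairs of
the evaluation pools at a fixed parameter combination (all five maxima by
default; best-of-32 is available by config).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import build_hull, separation_score, strip_envelope
from .params import EbssPropensities, pool_points
from .pools import PeptidePool
from .scales import AA_ALPHABETICAL, HydrophobicityScale

#: Pools used by the published fitness evaluation (digest-derived).
DEFAULT_EVAL_POOL_LABELS = ("dd-sheet", "dd-helix", "dd-random", "krtm-sheet", "krtm-helix")


class EvolutionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# random scales

def random_scales(
    corpus: Sequence[HydrophobicityScale], n: int = 200, seed: int = 0
) -> list[HydrophobicityScale]:
    """*n* scales with values uniform in the corpus-wide [min, max] interval."""
    if not corpus:
        raise EvolutionError("scale corpus is empty")
    lo = min(min(s.values.values()) for s in corpus)
    hi = max(max(s.values.values()) for s in corpus)
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        vals = dict(zip(AA_ALPHABETICAL, rng.uniform(lo, hi, size=20)))
        out.append(
            HydrophobicityScale(
                id=f"rand{i:04d}", name=f"random scale {i}", category="random", values=vals
            )
        )
    return out


def corpus_interval(corpus: Sequence[HydrophobicityScale]) -> tuple[float, float]:
    lo = min(min(s.values.values()) for s in corpus)
    hi = max(max(s.values.values()) for s in corpus)
    return lo, hi


# ---------------------------------------------------------------------------
# fitness

@dataclass
class FitnessConfig:
    """Configuration of the separation-based fitness function.

    Envelope stripping defaults to off here: at desk-scale evaluation pools
    (tens of peptides) most points of a 5-D cloud sit on its hull, so one
    strip collapses the cloud; dense-cloud pipelines can re-enable it.

    The default combination mask is 8 (max EBSS, max alternating, max
    moment-alpha, MIN moment-beta, max average): a mask picking the same
    extremum of both the alternating parameter and the 180-degree moment
    duplicates a coordinate (the two share one closed form) and collapses
    the cloud to a hyperplane, so the all-maxima mask is unusable for
    volume-based scoring.
    """

    combo: int = 8
    best_of_32: bool = False
    strip: bool = False
    mc_samples: int = 4000
    window_len: int = 10
    ebss_propensities: EbssPropensities | None = None
    seed: int = 0

    def props(self) -> EbssPropensities:
        if self.ebss_propensities is None:
            self.ebss_propensities = EbssPropensities.default()
        return self.ebss_propensities


def fitness(
    scale: HydrophobicityScale,
    eval_pools: Mapping[str, PeptidePool],
    config: FitnessConfig | None = None,
) -> float:
    """Mean separation score S over all unordered pairs of the eval pools."""
    config = config or FitnessConfig()
    labels = sorted(eval_pools)
    if len(labels) < 2:
        raise EvolutionError("need at least 2 evaluation pools")
    combos = range(32) if config.best_of_32 else [config.combo]
    props = config.props()
    # cache clouds per (pool, combo)
    clouds: dict[tuple[str, int], object] = {}
    for label in labels:
        for combo in combos:
            pts = pool_points(
                eval_pools[label], scale, combo, props, config.window_len
            )
            if len(pts) < 6:
                raise EvolutionError(
                    f"pool {label!r} has only {len(pts)} usable peptides"
                )
            cloud = build_hull(pts)
            if config.strip:
                cloud, _ = strip_envelope(cloud)
            clouds[(label, combo)] = cloud
    pair_scores = []
    for pa, pb in itertools.combinations(labels, 2):
        per_combo = [
            separation_score(
                clouds[(pa, c)], clouds[(pb, c)],
                method="mc", mc_samples=config.mc_samples, seed=config.seed,
            ).S
            for c in combos
        ]
        pair_scores.append(max(per_combo))
    return float(np.mean(pair_scores))


# ---------------------------------------------------------------------------
# schedule

@dataclass(frozen=True)
class Move:
    """One child's perturbation: amino acid and signed magnitude interval."""

    aa: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if self.aa not in AA_ALPHABETICAL:
            raise EvolutionError(f"unknown amino acid {self.aa!r} in schedule")
        if self.low >= self.high:
            raise EvolutionError(f"empty interval [{self.low}, {self.high}]")


@dataclass(frozen=True)
class EvoRound:
    name: str
    moves: tuple[Move, ...]


def default_schedule() -> list[EvoRound]:
    """The published six-round schedule (child counts 1000, 1000, 600, 600, 400, 1000)."""
    rounds = [
        EvoRound("evo1", tuple(
            Move(aa, 0.001, 5.0) for aa in AA_ALPHABETICAL for _ in range(50)
        )),
        EvoRound("evo2", tuple(
            Move(aa, -5.0, -0.001) for aa in AA_ALPHABETICAL for _ in range(50)
        )),
        EvoRound("evo3", tuple(
            [Move(aa, 0.001, 10.0) for aa in "EY" for _ in range(100)]
            + [Move(aa, -10.0, -0.001) for aa in "AHFL" for _ in range(100)]
        )),
        EvoRound("evo4", tuple(
            [Move("E", 0.001, 20.0) for _ in range(200)]
            + [Move(aa, -20.0, -0.001) for aa in "AH" for _ in range(200)]
        )),
        EvoRound("evo5", tuple(Move("E", 0.001, 40.0) for _ in range(400))),
        EvoRound("evo6", tuple(
            [Move(aa, 0.001, 5.0) for aa in AA_ALPHABETICAL for _ in range(25)]
            + [Move(aa, -5.0, -0.001) for aa in AA_ALPHABETICAL for _ in range(25)]
        )),
    ]
    return rounds


def scaled_schedule(children_per_round: int = 50) -> list[EvoRound]:
    """Desk-scale analogue of the default schedule with *children_per_round*
    children per round, cycling through each round's amino-acid set."""

    def cycle_moves(entries: list[tuple[str, float, float]], n: int) -> tuple[Move, ...]:
        it = itertools.cycle(entries)
        return tuple(Move(aa, lo, hi) for aa, lo, hi in itertools.islice(it, n))

    n = children_per_round
    return [
        EvoRound("evo1", cycle_moves([(aa, 0.001, 5.0) for aa in AA_ALPHABETICAL], n)),
        EvoRound("evo2", cycle_moves([(aa, -5.0, -0.001) for aa in AA_ALPHABETICAL], n)),
        EvoRound("evo3", cycle_moves(
            [(aa, 0.001, 10.0) for aa in "EY"] + [(aa, -10.0, -0.001) for aa in "AHFL"], n
        )),
        EvoRound("evo4", cycle_moves(
            [("E", 0.001, 20.0)] + [(aa, -20.0, -0.001) for aa in "AH"], n
        )),
        EvoRound("evo5", cycle_moves([("E", 0.001, 40.0)], n)),
        EvoRound("evo6", cycle_moves(
            [(aa, 0.001, 5.0) for aa in AA_ALPHABETICAL]
            + [(aa, -5.0, -0.001) for aa in AA_ALPHABETICAL], n
        )),
    ]


# ---------------------------------------------------------------------------
# the evolutionary loop

@dataclass
class EvolutionState:
    rounds: list[str]
    best_trajectory: list[tuple[str, float]]   # (round name, best fitness so far)
    best_scale: HydrophobicityScale
    fitness_by_round: dict[str, list[float]]   # all child fitnesses per round
    influence: pd.DataFrame | None             # per-AA report after evo1+evo2
    rng_seed: int
    value_interval: tuple[float, float]


def evolve(
    corpus: Sequence[HydrophobicityScale],
    eval_pools: Mapping[str, PeptidePool],
    schedule: Sequence[EvoRound] | None = None,
    seed: int = 0,
    n_random: int = 200,
    config: FitnessConfig | None = None,
) -> EvolutionState:
    """Run the full random-then-hill-climb optimisation with elitism.

    Round 0 scores *n_random* random scales; each subsequent round perturbs
    the current best scale (one amino acid per child) and keeps the argmax
    of children plus parent, so the best-fitness trajectory never decreases.
    After the two broad rounds an influence report ranks amino acids by the
    mean fitness change of the top-100 children touching them.
    """
    if schedule is None:
        schedule = default_schedule()
    config = config or FitnessConfig()
    interval = corpus_interval(corpus)
    rng = np.random.default_rng(seed)

    population = random_scales(corpus, n=n_random, seed=seed)
    fits = [fitness(s, eval_pools, config) for s in population]
    best_i = int(np.argmax(fits))
    best_scale, best_fit = population[best_i], fits[best_i]
    trajectory = [("random", best_fit)]
    fitness_by_round: dict[str, list[float]] = {"random": list(fits)}
    rounds_run = ["random"]
    broad_children: list[tuple[str, float, float]] = []  # (aa, delta, child fitness)

    gen = 0
    for rnd in schedule:
        child_fits: list[float] = []
        round_best_scale, round_best_fit = best_scale, best_fit
        for move in rnd.moves:
            delta = float(rng.uniform(move.low, move.high))
            vals = dict(best_scale.values)
            vals[move.aa] = vals[move.aa] + delta
            gen += 1
            child = HydrophobicityScale(
                id=f"evo{gen:05d}", name=f"{rnd.name} child ({move.aa}{delta:+.3f})",
                category="evolved", values=vals,
            )
            f = fitness(child, eval_pools, config)
            child_fits.append(f)
            if rnd.name in ("evo1", "evo2"):
                broad_children.append((move.aa, delta, f))
            if f > round_best_fit:
                round_best_scale, round_best_fit = child, f
        best_scale, best_fit = round_best_scale, round_best_fit  # elitism
        trajectory.append((rnd.name, best_fit))
        fitness_by_round[rnd.name] = child_fits
        rounds_run.append(rnd.name)

    influence = _influence_report(broad_children, trajectory[0][1]) if broad_children else None
    return EvolutionState(
        rounds=rounds_run,
        best_trajectory=trajectory,
        best_scale=best_scale,
        fitness_by_round=fitness_by_round,
        influence=influence,
        rng_seed=seed,
        value_interval=interval,
    )


def _influence_report(
    broad_children: list[tuple[str, float, float]], baseline: float, top_n: int = 100
) -> pd.DataFrame:
    """Rank amino acids by mean |fitness gain| among the top broad-round children."""
    top = sorted(broad_children, key=lambda t: -t[2])[:top_n]
    rows = []
    for aa in AA_ALPHABETICAL:
        mine = [(delta, f) for a, delta, f in top if a == aa]
        if not mine:
            continue
        gains = [f - baseline for _, f in mine]
        rows.append(
            {
                "aa": aa,
                "n_top_children": len(mine),
                "mean_gain": float(np.mean(gains)),
                "mean_abs_gain": float(np.mean(np.abs(gains))),
                "mean_delta_sign": float(np.mean(np.sign([d for d, _ in mine]))),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values("mean_abs_gain", ascending=False).reset_index(drop=True)


def trajectory_table(state: EvolutionState) -> pd.DataFrame:
    return pd.DataFrame(state.best_trajectory, columns=["round", "best_fitness"])


def scale_to_two_column(scale: HydrophobicityScale) -> str:
    lines = [f"#id: {scale.id}", f"#name: {scale.name}", f"#category: {scale.category}"]
    lines += [f"{aa}\t{scale.values[aa]:.6g}" for aa in AA_ALPHABETICAL]
    return "\n".join(lines) + "\n"
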