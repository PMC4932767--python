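"""Scenario enumeration and aggregate separation analyses.

A *scenario* is (hydrophobicity scale, 5-bit parameter combination, pool
pair).  Evaluating it builds the two 5-D clouds, strips the convex envelope
once, and computes the separation score.  On top of single scenarios this
module provides the per-scale overall score, the pairwise best-S matrix,
cluster-averaged scores and the parameter-influence statistic over the
best-separated fraction of all scenarios.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import DEFAULT_MC_SAMPLES, SeparationResult, build_hull, separation_score, strip_envelope
from .params import EbssPropensities, WINDOW_LENGTH_DEFAULT, pool_points
from .pools import PeptidePool
from .scales import HydrophobicityScale, ScaleClustering

ALL_COMBOS = tuple(range(32))


class SeparationError(ValueError):
    pass


@dataclass(frozen=True)
class ScenarioSpec:
    """One scored scenario: a scale, a max/min combination mask, a pool pair."""

    scale_id: str
    combo: int
    pool_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if not (0 <= self.combo <= 31):
            raise SeparationError(f"combo {self.combo} outside 0..31")

    def sort_key(self) -> tuple:
        return (self.scale_id, self.combo, self.pool_pair)


@dataclass
class SeparationConfig:
    window_len: int = WINDOW_LENGTH_DEFAULT
    ebss_propensities: EbssPropensities | None = None
    strip: bool = True
    method: str = "mc"
    mc_samples: int = DEFAULT_MC_SAMPLES
    seed: int = 0

    def props(self) -> EbssPropensities:
        if self.ebss_propensities is None:
            self.ebss_propensities = EbssPropensities.default()
        return self.ebss_propensities


def _scenario_seed(spec: ScenarioSpec, base_seed: int) -> int:
    key = f"{spec.scale_id}|{spec.combo}|{spec.pool_pair[0]}|{spec.pool_pair[1]}"
    return (zlib.crc32(key.encode()) ^ (base_seed & 0x7FFFFFFF)) & 0x7FFFFFFF


def evaluate_scenario(
    spec: ScenarioSpec,
    pools: Mapping[str, PeptidePool],
    scales: Mapping[str, HydrophobicityScale],
    config: SeparationConfig | None = None,
) -> SeparationResult:
    """Score one scenario; deterministic for a fixed config seed.

    Both pools' peptides become 5-D points via the combination mask, the
    hulls are built, the convex envelope is stripped once (config flag), and
    the separation score is computed on the retained points.
    """
    config = config or SeparationConfig()
    try:
        scale = scales[spec.scale_id]
    except KeyError:
        raise SeparationError(f"unknown scale id {spec.scale_id!r}") from None
    clouds = []
    for label in spec.pool_pair:
        try:
            pool = pools[label]
        except KeyError:
            raise SeparationError(f"unknown pool label {label!r}") from None
        pts = pool_points(pool, scale, spec.combo, config.props(), config.window_len)
        if len(pts) < 6:
            raise SeparationError(
                f"pool {label!r} has only {len(pts)} usable peptides; "
                "a 5-D cloud needs at least 6"
            )
        cloud = build_hull(pts)
        if config.strip:
            cloud, _ = strip_envelope(cloud)
        clouds.append(cloud)
    return separation_score(
        clouds[0], clouds[1],
        method=config.method, mc_samples=config.mc_samples,
        seed=_scenario_seed(spec, config.seed),
    )


def sweep(
    pools: Mapping[str, PeptidePool],
    scales: Mapping[str, HydrophobicityScale],
    combos: Sequence[int] = ALL_COMBOS,
    config: SeparationConfig | None = None,
) -> list[tuple[ScenarioSpec, SeparationResult]]:
    """All scenarios over every unordered pool pair, scale and combo."""
    labels = sorted(pools)
    out = []
    for scale_id in sorted(scales):
        for combo in combos:
            for pa, pb in itertools.combinations(labels, 2):
                spec = ScenarioSpec(scale_id=scale_id, combo=combo, pool_pair=(pa, pb))
                out.append((spec, evaluate_scenario(spec, pools, scales, config)))
    return out


def results_table(results: Iterable[tuple[ScenarioSpec, SeparationResult]]) -> pd.DataFrame:
    rows = []
    for spec, res in results:
        row = {
            "pool_a": spec.pool_pair[0], "pool_b": spec.pool_pair[1],
            "scale_id": spec.scale_id, "combo": spec.combo,
        }
        row.update(res.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# aggregation

def scale_overall_score(
    scale_id: str,
    pools: Mapping[str, PeptidePool],
    scales: Mapping[str, HydrophobicityScale],
    combos: Sequence[int] = ALL_COMBOS,
    mode: str = "best-combo-mean",
    config: SeparationConfig | None = None,
    fixed_combo: int = 0,
) -> float:
    """One overall separation value for a scale over all pool pairs.

    Modes: ``best-combo-mean`` (per pair take the max S over combos, then
    average over pairs; default), ``mean-mean`` (average over combos and
    pairs), ``fixed-combo`` (single mask *fixed_combo*).
    """
    if len(pools) < 2:
        raise SeparationError("need at least 2 pools")
    labels = sorted(pools)
    pair_scores = []
    for pa, pb in itertools.combinations(labels, 2):
        use_combos = [fixed_combo] if mode == "fixed-combo" else list(combos)
        s_vals = [
            evaluate_scenario(
                ScenarioSpec(scale_id, c, (pa, pb)), pools, scales, config
            ).S
            for c in use_combos
        ]
        if mode == "best-combo-mean":
            pair_scores.append(max(s_vals))
        elif mode in ("mean-mean", "fixed-combo"):
            pair_scores.append(float(np.mean(s_vals)))
        else:
            raise SeparationError(f"unknown aggregation mode {mode!r}")
    return float(np.mean(pair_scores))


def pairwise_best_matrix(
    pools: Mapping[str, PeptidePool],
    scales: Mapping[str, HydrophobicityScale],
    combos: Sequence[int] = ALL_COMBOS,
    config: SeparationConfig | None = None,
) -> pd.DataFrame:
    """Symmetric pool-by-pool matrix of the best S over scales x combos.

    Each cell holds the best score; the companion columns of the long format
    (via ``sweep``) retain provenance.  The diagonal is 0 by convention.
    """
    if len(pools) < 2:
        raise SeparationError("need at least 2 pools")
    labels = sorted(pools)
    best = pd.DataFrame(0.0, index=labels, columns=labels)
    provenance = pd.DataFrame("", index=labels, columns=labels)
    for pa, pb in itertools.combinations(labels, 2):
        best_s, best_who = -1.0, ""
        for scale_id in sorted(scales):
            for combo in combos:
                s = evaluate_scenario(
                    ScenarioSpec(scale_id, combo, (pa, pb)), pools, scales, config
                ).S
                if s > best_s:
                    best_s, best_who = s, f"{scale_id}/combo{combo}"
        best.loc[pa, pb] = best.loc[pb, pa] = best_s
        provenance.loc[pa, pb] = provenance.loc[pb, pa] = best_who
    best.attrs["provenance"] = provenance
    return best


def cluster_average_score(
    clustering: ScaleClustering, per_scale_scores: Mapping[str, float]
) -> dict[str, float]:
    """Arithmetic mean of the member scales' overall scores per cluster."""
    for sid in per_scale_scores:
        if sid not in clustering.clusters:
            raise SeparationError(f"scale {sid!r} not present in the clustering")
    sums: dict[str, list[float]] = {}
    for sid, score in per_scale_scores.items():
        sums.setdefault(clustering.clusters[sid], []).append(score)
    return {label: float(np.mean(v)) for label, v in sorted(sums.items())}


def parameter_influence(
    all_scenarios: Sequence[tuple[ScenarioSpec, float]],
    top_fraction: float = 0.05,
) -> np.ndarray:
    """|observed - expected| frequency of each of the 10 parameter choices.

    Scenarios are ranked by S (ties broken by scale id, combo, pair order);
    the top *top_fraction* define the observed frequencies of each (parameter,
    max/min) choice, compared against the frequencies over all scenarios.
    """
    n = len(all_scenarios)
    if n < 20:
        raise SeparationError(f"need >= 20 scenarios, got {n}")
    ranked = sorted(all_scenarios, key=lambda t: (-t[1], t[0].sort_key()))
    n_top = max(1, int(n * top_fraction))
    if n_top == 0:
        raise SeparationError("top scenario set is empty")

    def choice_freqs(subset: Sequence[tuple[ScenarioSpec, float]]) -> np.ndarray:
        freq = np.zeros(10)
        for spec, _ in subset:
            for k in range(5):
                bit = (spec.combo >> k) & 1
                freq[2 * k + bit] += 1
        return freq / len(subset)

    observed = choice_freqs(ranked[:n_top])
    expected = choice_freqs(all_scenarios)
    return np.abs(observed - expected)


def influence_table(influence: np.ndarray) -> pd.DataFrame:
    from .params import PARAMETER_NAMES

    return pd.DataFrame(
        {"index": range(10), "parameter": PARAMETER_NAMES, "influence": influence}
    )
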