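"""Synthetic two-condition intensity studies with planted differential signatures.

The generator emulates the statistical shape the ranking pipeline assumes:
positive, linear-scale intensities (log-normal, so some values fall below the
pooled lower quartile and exercise the clamping branches); paired
experiment/control samples; and per-condition planted sets of up- and
down-regulated probes.  One "disease" condition is accompanied by several
perturbation conditions; a designated perturbation reuses a controllable
fraction of the disease's planted probes in the same directions, the rest
act as decoys with their own independently drawn planted sets.  Every draw
flows from one integer seed through numpy's SeedSequence spawning, so a
study is reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix, PairEntry, PairManifest
import pandas as pd

__all__ = [
    "SimulationConfig",
    "simulate_control",
    "simulate_perturbation",
    "simulate_study",
]

DISEASE_LABEL = "disease"
DESIGNATED_LABEL = "designated"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale study: a 2000-probe universe, a disease
    condition plus 20 perturbations (one designated, 19 decoys) with three
    replicate pairs each, 100 up- and 100 down-regulated planted probes per
    condition at four-fold change under 0.2 multiplicative log-normal noise,
    and the designated perturbation sharing 80% of the disease's planted
    probes.
    """

    n_probes: int = 2000
    n_conditions: int = 21
    replicates_per_condition: int = 3
    signature_size_planted: int = 100
    fold_change: float = 4.0
    noise_sigma: float = 0.2
    overlap_fraction: float = 0.8
    seed: int = 0
    log_mean: float = 6.0
    log_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_probes < 4:
            raise ValueError("n_probes must be at least 4")
        if self.n_conditions < 2:
            raise ValueError("need the disease plus at least one perturbation")
        if self.replicates_per_condition < 1:
            raise ValueError("replicates_per_condition must be >= 1")
        if 2 * self.signature_size_planted > self.n_probes:
            raise ValueError("planted up+down sets exceed the probe universe")
        if not self.fold_change > 1:
            raise ValueError("fold_change must be > 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not 0 <= self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_control(
    n_probes: int, seed, log_mean: float = 6.0, log_sd: float = 1.0
) -> np.ndarray:
    """I.i.d. log-normal baseline intensities (log-mean 6, log-sd 1 by default)."""
    if n_probes < 4:
        raise ValueError("n_probes must be at least 4")
    rng = _as_rng(seed)
    return rng.lognormal(mean=log_mean, sigma=log_sd, size=n_probes)


def simulate_perturbation(
    control: np.ndarray,
    up_probes: Sequence[int],
    down_probes: Sequence[int],
    fold_change: float,
    noise_sigma: float,
    seed,
) -> np.ndarray:
    """Apply a planted fold change and multiplicative log-normal noise.

    ``up_probes`` / ``down_probes`` index positions of the control vector;
    up probes are multiplied by ``fold_change``, down probes divided by it,
    then the whole vector is multiplied element-wise by exp(N(0, sigma)).
    """
    up = np.asarray(up_probes, dtype=int)
    down = np.asarray(down_probes, dtype=int)
    if np.intersect1d(up, down).size:
        raise ValueError("up and down probe sets overlap")
    rng = _as_rng(seed)
    experiment = np.asarray(control, dtype=float).copy()
    experiment[up] *= fold_change
    experiment[down] /= fold_change
    if noise_sigma > 0:
        experiment *= np.exp(rng.normal(0.0, noise_sigma, size=experiment.size))
    return experiment


def _plant_sets(config: SimulationConfig, rng: np.random.Generator):
    """Choose planted up/down index sets per condition.

    The disease's sets are drawn first; the designated perturbation reuses
    ``overlap_fraction`` of each (same direction) and fills the remainder
    from the non-disease pool; each decoy draws its sets independently from
    that pool (decoys may overlap one another, never the disease).
    """
    k = config.signature_size_planted
    perm = rng.permutation(config.n_probes)
    disease_up, disease_down = perm[:k], perm[k : 2 * k]
    pool = perm[2 * k :]

    n_shared = int(round(config.overlap_fraction * k))
    n_novel = k - n_shared
    needed = max(2 * n_novel, 2 * k if config.n_conditions > 2 else 0)
    if needed > pool.size:
        raise ValueError("planted sets cannot fit disjointly in the probe universe")

    def draw_pool(size: int) -> np.ndarray:
        return rng.choice(pool, size=size, replace=False)

    novel = draw_pool(2 * n_novel)
    designated_up = np.concatenate(
        [rng.choice(disease_up, size=n_shared, replace=False), novel[:n_novel]]
    )
    designated_down = np.concatenate(
        [rng.choice(disease_down, size=n_shared, replace=False), novel[n_novel:]]
    )

    planted = {
        DISEASE_LABEL: (disease_up, disease_down),
        DESIGNATED_LABEL: (designated_up.astype(int), designated_down.astype(int)),
    }
    for i in range(config.n_conditions - 2):
        both = draw_pool(2 * k)
        planted[f"decoy{i + 1:02d}"] = (both[:k], both[k:])
    return planted


def simulate_study(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, PairManifest, dict]:
    """Generate one full study: matrix, pairing manifest and ground truth.

    Returns the probe × sample intensity matrix (one experiment and one
    control column per replicate pair), the manifest pairing them by
    condition, and a ground-truth dict mapping each condition label to its
    planted ``up`` / ``down`` probe-id lists (plus the designated label).
    """
    root = np.random.SeedSequence(config.seed)
    layout_seed, *pair_seeds = root.spawn(
        1 + config.n_conditions * config.replicates_per_condition
    )
    rng = np.random.default_rng(layout_seed)

    width = len(str(config.n_probes - 1))
    probe_ids = np.array([f"P{i:0{width}d}" for i in range(config.n_probes)])
    planted = _plant_sets(config, rng)

    columns: dict[str, np.ndarray] = {}
    entries: list[PairEntry] = []
    pair_iter = iter(pair_seeds)
    for condition, (up, down) in planted.items():
        for r in range(1, config.replicates_per_condition + 1):
            pair_rng = np.random.default_rng(next(pair_iter))
            control = simulate_control(
                config.n_probes, pair_rng, config.log_mean, config.log_sd
            )
            experiment = simulate_perturbation(
                control, up, down, config.fold_change, config.noise_sigma, pair_rng
            )
            exp_id = f"{condition}_r{r}_exp"
            ctl_id = f"{condition}_r{r}_ctl"
            columns[exp_id] = experiment
            columns[ctl_id] = control
            entries.append(
                PairEntry(exp_id, ctl_id, condition, f"{condition}_ds{r}")
            )

    matrix = ExpressionMatrix(pd.DataFrame(columns, index=probe_ids))
    manifest = PairManifest(tuple(entries))
    ground_truth = {
        "designated_label": DESIGNATED_LABEL,
        "disease_label": DISEASE_LABEL,
        "planted": {
            label: {
                "up": probe_ids[up].tolist(),
                "down": probe_ids[down].tolist(),
            }
            for label, (up, down) in planted.items()
        },
    }
    return matrix, manifest, ground_truth
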