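"""Frozen study-condition scenarios used by tests and the acceptance script.

Each scenario fixes the synthetic community's conditions — variant
counts, time span, sequencing depth, error rate, and latent-dynamics
parameters — once, so every consumer exercises the same simulated study.
Seeds are the only thing callers vary.

Conditions:

* ``recovery``: 3 families × 3 variants differing at 1–3 positions,
  60 days, 5,000 reads/day, 0.1% per-base substitution error — the
  parameter-recovery benchmark for the decomposition.
* ``planted_pair``: 10 variants of one family observed for 60 days at
  depth 20,000.  Variants 1+2 share latent factor 0 (sd 0.3, both +1):
  the planted correlated pair.  Variants 3+4 share factor 1 (sd 0.8,
  signs ±1) around a high common baseline (1.5 log-units), so the two
  trade a jointly large share: the planted anti-correlated pair.  Six
  background variants fluctuate independently (sd 0.4).  All latent
  processes are mean-reverting AR(1) walks (coefficient 0.85), keeping
  the community in a stationary dynamic equilibrium.
* ``dominance_switch``: two variants; the initially dominant one
  (baseline 3 log-units) is overtaken by a logistic ramp (amplitude 6,
  rate 1/day) centred on day 30; private noise sd 0.15.
* ``null``: independent i.i.d. standard-normal trajectories with no
  structure at all, for significance calibration.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from oligodyn.panel import ReferencePanel
from oligodyn.synthetic import DynamicsSpec, TruthTable, emit_reads, generate_variant_panel, simulate_trajectories

RECOVERY = dict(
    n_families=3,
    variants_per_family=3,
    n_diff_positions=3,
    n_days=60,
    depth=5_000,
    error_rate=0.001,
    read_length=130,
    fluctuation_sd=0.3,
    ar1_coeff=0.9,
)

PLANTED_PAIR = dict(
    n_variants=10,
    n_days=60,
    depth=20_000,
    ar1=0.85,
    corr_factor_sd=0.3,
    anti_factor_sd=0.8,
    anti_baseline=1.5,
    background_sd=0.4,
)

DOMINANCE_SWITCH = dict(
    n_days=60,
    switch_day=30,
    switch_rate=1.0,
    switch_amplitude=6.0,
    old_baseline=3.0,
    noise_sd=0.15,
    ar1=0.9,
    depth=5_000,
)


def recovery_dataset(seed: int, out_dir: str | Path) -> tuple[ReferencePanel, TruthTable, Path]:
    """Emit the parameter-recovery dataset; returns (panel, truth, manifest path)."""
    c = RECOVERY
    panel = generate_variant_panel(
        c["n_families"], c["variants_per_family"], c["n_diff_positions"],
        seq_length=c["read_length"], seed=seed,
    )
    specs = {
        e.name: DynamicsSpec(fluctuation_sd=c["fluctuation_sd"], ar1_coeff=c["ar1_coeff"])
        for e in panel
    }
    truth = simulate_trajectories(panel, specs, c["n_days"], seed=seed + 1)
    manifest, _ = emit_reads(
        truth, c["depth"], c["error_rate"], c["read_length"], out_dir, seed=seed + 2
    )
    panel.to_fasta(Path(out_dir) / "panel.fasta")
    return panel, truth, manifest


def planted_pair_counts(seed: int) -> tuple[pd.DataFrame, tuple[str, str], tuple[str, str]]:
    """Realized count trajectories with one correlated and one anti-correlated pair.

    Returns (counts matrix [variants × days], correlated pair ids,
    anti-correlated pair ids).
    """
    c = PLANTED_PAIR
    panel = generate_variant_panel(1, c["n_variants"], 24, 130, seed=seed)
    names = [e.name for e in panel]
    specs = {
        names[0]: DynamicsSpec(latent_factor_id=0, latent_sign=1),
        names[1]: DynamicsSpec(latent_factor_id=0, latent_sign=1),
        names[2]: DynamicsSpec(baseline=c["anti_baseline"], latent_factor_id=1, latent_sign=1),
        names[3]: DynamicsSpec(baseline=c["anti_baseline"], latent_factor_id=1, latent_sign=-1),
    }
    for n in names[4:]:
        specs[n] = DynamicsSpec(fluctuation_sd=c["background_sd"], ar1_coeff=c["ar1"])
    truth = simulate_trajectories(
        panel, specs, c["n_days"], seed=seed + 1,
        factor_sd={0: c["corr_factor_sd"], 1: c["anti_factor_sd"]},
        factor_ar1=c["ar1"],
    )
    rng = np.random.default_rng(seed + 2)
    counts = np.stack(
        [
            rng.multinomial(c["depth"], truth.abundances[:, d] / truth.abundances[:, d].sum())
            for d in range(c["n_days"])
        ],
        axis=1,
    )
    days = list(range(c["n_days"]))
    matrix = pd.DataFrame(counts, index=names, columns=days)
    return matrix, (names[0], names[1]), (names[2], names[3])


def dominance_switch_shares(seed: int, with_switch: bool = True) -> pd.DataFrame:
    """Within-group percent shares for the dominance-switch benchmark.

    ``with_switch=False`` yields the stable-dominance control (no ramp).
    Shares are realized from multinomial counts at the scenario depth.
    """
    c = DOMINANCE_SWITCH
    panel = generate_variant_panel(1, 2, 2, 130, seed=seed)
    names = [e.name for e in panel]
    specs = {
        names[0]: DynamicsSpec(
            baseline=c["old_baseline"], fluctuation_sd=c["noise_sd"], ar1_coeff=c["ar1"]
        ),
        names[1]: DynamicsSpec(
            baseline=0.0,
            fluctuation_sd=c["noise_sd"],
            ar1_coeff=c["ar1"],
            switch_day=c["switch_day"] if with_switch else None,
            switch_rate=c["switch_rate"],
            switch_amplitude=c["switch_amplitude"],
        ),
    }
    truth = simulate_trajectories(panel, specs, c["n_days"], seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    counts = np.stack(
        [rng.multinomial(c["depth"], truth.abundances[:, d]) for d in range(c["n_days"])],
        axis=1,
    )
    pct = 100.0 * counts / counts.sum(axis=0)
    return pd.DataFrame(pct, index=names, columns=list(range(c["n_days"])))


def null_trajectories(seed: int, n_trajectories: int = 100, n_days: int = 60) -> pd.DataFrame:
    """Independent i.i.d. standard-normal trajectories (no real structure)."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_trajectories, n_days))
    return pd.DataFrame(
        X, index=[f"traj_{i:03d}" for i in range(n_trajectories)], columns=list(range(n_days))
    )
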