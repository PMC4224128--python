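"""Synthetic amplicon time series with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: families of near-identical 16S sequence variants (1–24 differing
positions within a family, < 90% identity between families), daily
relative-abundance trajectories driven by log-scale latent processes
(stable dominance, abrupt logistic replacements, correlated and
anti-correlated pairs via shared latent factors), multinomial read
sampling at a fixed per-sample depth, and i.i.d. per-base substitution
error on fixed-length reads.

Latent model, per variant v and day t:

    lambda_v(t) = b_v + W_v(t) + s_v * F_{g(v)}(t) + A_v * sigmoid(k_v * (t - t0_v))

where b_v is the baseline log-abundance, W_v a Gaussian AR(1) walk with
innovation sd sigma_v (coefficient 1 = pure random walk; below 1,
mean-reverting), F_g a shared-factor walk entering with sign
s_v, and the last term an optional logistic dominance ramp of amplitude
A_v (log-units), rate k_v (per day), centred on switch day t0_v.  Daily
relative abundances are the softmax of lambda over variants, so every day
is a valid composition by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit, softmax

from oligodyn._seq import ALPHABET, encode, decode
from oligodyn.panel import PanelEntry, ReferencePanel

MANIFEST_COLUMNS = ("sample_id", "subject_id", "day", "path", "n_reads")

_CROSS_FAMILY_MAX_IDENTITY = 90.0  # %, matches the classifier's identity floor


@dataclass
class DynamicsSpec:
    """Latent-dynamics parameters for one sequence variant.

    Parameters
    ----------
    baseline:
        Baseline log-abundance (unitless, softmax scale).
    fluctuation_sd:
        Innovation sd of the variant's private log-scale random walk.
    switch_day, switch_rate, switch_amplitude:
        Optional logistic dominance ramp: amplitude (log-units) reached
        around ``switch_day`` at steepness ``switch_rate`` per day.  A
        negative amplitude models loss of dominance.
    latent_factor_id, latent_sign:
        Variants sharing a factor id receive the same shared random-walk
        perturbation, multiplied by ±1 — the generator's correlated /
        anti-correlated pairs.
    ar1_coeff:
        AR(1) coefficient of the private fluctuation process: 1.0 is a
        pure random walk; values below 1 give a mean-reverting walk
        (an Ornstein-Uhlenbeck-like stationary equilibrium around the
        baseline rather than unbounded drift).
    """

    baseline: float = 0.0
    fluctuation_sd: float = 0.0
    switch_day: int | None = None
    switch_rate: float = 1.0
    switch_amplitude: float = 6.0
    latent_factor_id: int | None = None
    latent_sign: int = 1
    ar1_coeff: float = 1.0

    def __post_init__(self) -> None:
        if self.fluctuation_sd < 0:
            raise ValueError("fluctuation_sd must be >= 0")
        if not (0.0 <= self.ar1_coeff <= 1.0):
            raise ValueError("ar1_coeff must be in [0, 1]")
        if self.switch_day is not None and self.switch_rate <= 0:
            raise ValueError("switch_rate must be > 0 when switch_day is set")
        if self.latent_sign not in (-1, 1):
            raise ValueError("latent_sign must be +1 or -1")
        if self.latent_factor_id is not None and self.latent_factor_id < 0:
            raise ValueError(f"unknown latent_factor_id {self.latent_factor_id}")


@dataclass
class TruthTable:
    """Ground truth for a simulated time series.

    ``abundances`` is variants × days with each day's column summing to 1;
    ``realized_counts`` (variants × sampled days) and ``window_sequences``
    are filled in by :func:`emit_reads`.
    """

    variant_names: list[str]
    sequences: list[str]
    n_days: int
    missing_days: frozenset[int]
    abundances: np.ndarray
    specs: dict[str, DynamicsSpec]
    seed: int
    window_sequences: list[str] | None = None
    realized_counts: np.ndarray | None = None
    depth_per_sample: int | None = None

    @property
    def sampled_days(self) -> list[int]:
        return [d for d in range(self.n_days) if d not in self.missing_days]

    def windows(self, read_length: int) -> list[str]:
        """5' windows of the variant sequences at the given read length."""
        if any(len(s) < read_length for s in self.sequences):
            raise ValueError("read_length exceeds a variant sequence length")
        return [s[:read_length] for s in self.sequences]


def _random_family_base(rng: np.random.Generator, seq_length: int) -> np.ndarray:
    return rng.integers(0, 4, size=seq_length).astype(np.uint8)


def generate_variant_panel(
    n_families: int,
    variants_per_family: int,
    n_diff_positions: int,
    seq_length: int = 130,
    seed: int = 0,
) -> ReferencePanel:
    """Build a panel of variant families with controlled divergence.

    Within a family every pair of variants differs at between 1 and
    ``n_diff_positions`` positions (variants carry distinct base tuples at
    a fixed set of segregating positions); between families pairwise
    identity is below 90%, so family-level classification is unambiguous.
    """
    if n_families < 1 or variants_per_family < 1:
        raise ValueError("n_families and variants_per_family must be >= 1")
    if n_diff_positions < 1:
        raise ValueError("n_diff_positions must be >= 1")
    if seq_length < 130:
        raise ValueError("seq_length must be >= 130 (the fixed read length)")
    if n_diff_positions > seq_length:
        raise ValueError(
            f"seq_length {seq_length} too short to place {n_diff_positions} "
            "differing positions"
        )
    max_variants = 4 ** min(n_diff_positions, 16)
    if variants_per_family > max_variants:
        raise ValueError(
            f"{variants_per_family} variants need more than "
            f"{n_diff_positions} segregating 4-letter positions"
        )

    rng = np.random.default_rng(seed)
    entries: list[PanelEntry] = []
    family_variant_codes: list[list[np.ndarray]] = []

    for f in range(n_families):
        # resample the family base until it is < 90% identical to every
        # existing variant (random 130-mers are ~25% identical, so this
        # loop essentially never iterates)
        while True:
            base = _random_family_base(rng, seq_length)
            positions = np.sort(rng.choice(seq_length, size=n_diff_positions, replace=False))
            tuples: list[tuple[int, ...]] = [tuple(int(b) for b in base[positions])]
            seen = set(tuples)
            while len(tuples) < variants_per_family:
                cand = tuple(int(x) for x in rng.integers(0, 4, size=n_diff_positions))
                if cand not in seen:
                    seen.add(cand)
                    tuples.append(cand)
            variants = []
            for tup in tuples:
                codes = base.copy()
                codes[positions] = np.asarray(tup, dtype=np.uint8)
                variants.append(codes)
            ok = True
            for prev_family in family_variant_codes:
                for pv in prev_family:
                    for v in variants:
                        ident = 100.0 * np.mean(pv == v)
                        if ident >= _CROSS_FAMILY_MAX_IDENTITY:
                            ok = False
            if ok:
                break
        family_variant_codes.append(variants)
        fam = f"SynFamily{f + 1:02d}"
        for v_i, codes in enumerate(variants):
            entries.append(
                PanelEntry(
                    name=f"F{f + 1:02d}V{v_i + 1:02d}",
                    sequence=decode(codes),
                    family=fam,
                    genus=f"SynGenus{f + 1:02d}",
                    species=f"syn_sp_{f + 1:02d}_{v_i + 1:02d}",
                    taxon_id=f"SYN-{f + 1:03d}.{v_i + 1:02d}",
                )
            )
    return ReferencePanel(entries)


def simulate_trajectories(
    panel: ReferencePanel,
    specs: Mapping[str, DynamicsSpec],
    n_days: int,
    missing_days: Sequence[int] | frozenset[int] = frozenset(),
    seed: int = 0,
    factor_sd: float | Mapping[int, float] = 1.0,
    factor_ar1: float = 1.0,
) -> TruthTable:
    """Simulate daily true relative abundances for every panel variant.

    Every variant needs a :class:`DynamicsSpec`; shared latent factors are
    Gaussian random walks with innovation sd ``factor_sd`` (a single value
    or a per-factor-id mapping) drawn once per factor id and added to each
    member's log-abundance with its sign.
    Days listed in ``missing_days`` are flagged as unsampled (downstream
    interpolation is exercised on them) but their truth is still recorded.
    """
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    names = [e.name for e in panel]
    if set(specs) != set(names):
        mismatch = sorted(set(specs) ^ set(names))
        raise ValueError(f"specs must cover exactly the panel variants; mismatch: {mismatch}")
    missing_days = frozenset(int(d) for d in missing_days)
    if any(d < 0 or d >= n_days for d in missing_days):
        raise ValueError("missing_days outside 0..n_days-1")

    rng = np.random.default_rng(seed)
    factor_ids = sorted(
        {s.latent_factor_id for s in specs.values() if s.latent_factor_id is not None}
    )
    def _fsd(fid: int) -> float:
        if isinstance(factor_sd, Mapping):
            if fid not in factor_sd:
                raise ValueError(f"unknown latent_factor_id {fid}: no factor_sd given")
            return float(factor_sd[fid])
        return float(factor_sd)

    def _ar1_walk(innov: np.ndarray, coeff: float) -> np.ndarray:
        if coeff >= 1.0:
            return np.cumsum(innov)
        out = np.empty_like(innov)
        acc = 0.0
        for k, e in enumerate(innov):
            acc = coeff * acc + e
            out[k] = acc
        return out

    if not (0.0 <= factor_ar1 <= 1.0):
        raise ValueError("factor_ar1 must be in [0, 1]")
    factors = {
        fid: _ar1_walk(rng.normal(0.0, _fsd(fid), size=n_days), factor_ar1)
        for fid in factor_ids
    }

    t = np.arange(n_days, dtype=float)
    latent = np.empty((len(names), n_days))
    for i, name in enumerate(names):
        s = specs[name]
        walk = _ar1_walk(rng.normal(0.0, 1.0, size=n_days), s.ar1_coeff) * s.fluctuation_sd
        lam = s.baseline + walk
        if s.latent_factor_id is not None:
            lam = lam + s.latent_sign * factors[s.latent_factor_id]
        if s.switch_day is not None:
            lam = lam + s.switch_amplitude * expit(s.switch_rate * (t - s.switch_day))
        latent[i] = lam

    abundances = softmax(latent, axis=0)
    return TruthTable(
        variant_names=names,
        sequences=[e.sequence for e in panel],
        n_days=n_days,
        missing_days=missing_days,
        abundances=abundances,
        specs=dict(specs),
        seed=seed,
    )


def _mutate_reads(
    window_codes: np.ndarray, n: int, error_rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Tile a variant window n times and apply i.i.d. substitutions."""
    reads = np.tile(window_codes, (n, 1))
    if error_rate > 0.0:
        mask = rng.random(reads.shape) < error_rate
        hits = np.nonzero(mask)
        if hits[0].size:
            shift = rng.integers(1, 4, size=hits[0].size).astype(np.uint8)
            reads[hits] = (reads[hits] + shift) % 4
    return reads


def emit_reads(
    truth: TruthTable,
    depth_per_sample: int,
    error_rate: float,
    read_length: int,
    out_dir: str | Path,
    seed: int = 0,
    subject_id: str = "subj1",
) -> tuple[Path, Path]:
    """Write per-sample FASTA reads, a manifest TSV, and a truth JSON.

    Each sampled day draws variant read counts from a multinomial at the
    day's true composition, then emits every read as the variant's 5'
    window of ``read_length`` nt with i.i.d. substitutions at
    ``error_rate`` per base.  Output is byte-deterministic for a fixed
    (truth, seed).  Returns (manifest path, truth path).
    """
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    if depth_per_sample < 1:
        raise ValueError("depth_per_sample must be >= 1")
    windows = truth.windows(read_length)
    window_codes = [encode(w) for w in windows]

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        reads_dir = out_dir / "reads"
        reads_dir.mkdir(exist_ok=True)
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    rng = np.random.default_rng(seed)
    sampled = truth.sampled_days
    n_var = len(truth.variant_names)
    realized = np.zeros((n_var, len(sampled)), dtype=np.int64)
    manifest_rows = []
    decode_tbl = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)

    for j, day in enumerate(sampled):
        p = truth.abundances[:, day]
        counts = rng.multinomial(depth_per_sample, p / p.sum())
        realized[:, j] = counts
        sample_id = f"{subject_id}_d{day:03d}"
        fasta_rel = Path("reads") / f"{sample_id}.fasta"
        read_no = 0
        with open(out_dir / fasta_rel, "w") as fh:
            for v in range(n_var):
                if counts[v] == 0:
                    continue
                block = _mutate_reads(window_codes[v], int(counts[v]), error_rate, rng)
                chars = decode_tbl[block]
                for row in chars:
                    read_no += 1
                    fh.write(f">{sample_id}_r{read_no:06d}\n")
                    fh.write(row.tobytes().decode())
                    fh.write("\n")
        manifest_rows.append(
            (sample_id, subject_id, day, str(fasta_rel), depth_per_sample)
        )

    manifest_path = out_dir / "manifest.tsv"
    with open(manifest_path, "w") as fh:
        fh.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for row in manifest_rows:
            fh.write("\t".join(str(x) for x in row) + "\n")

    truth.window_sequences = windows
    truth.realized_counts = realized
    truth.depth_per_sample = depth_per_sample

    truth_path = out_dir / "truth.json"
    payload = {
        "seed": truth.seed,
        "emit_seed": seed,
        "subject_id": subject_id,
        "read_length": read_length,
        "error_rate": error_rate,
        "depth_per_sample": depth_per_sample,
        "n_days": truth.n_days,
        "missing_days": sorted(truth.missing_days),
        "sampled_days": sampled,
        "variant_names": truth.variant_names,
        "sequences": truth.sequences,
        "window_sequences": windows,
        "abundances": truth.abundances.tolist(),
        "realized_counts": realized.tolist(),
        "specs": {k: asdict(v) for k, v in truth.specs.items()},
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest_path, truth_path


def load_truth(path: str | Path) -> TruthTable:
    """Load a truth JSON written by :func:`emit_reads`."""
    with open(path) as fh:
        d = json.load(fh)
    tt = TruthTable(
        variant_names=d["variant_names"],
        sequences=d["sequences"],
        n_days=d["n_days"],
        missing_days=frozenset(d["missing_days"]),
        abundances=np.asarray(d["abundances"]),
        specs={k: DynamicsSpec(**v) for k, v in d["specs"].items()},
        seed=d["seed"],
        window_sequences=d["window_sequences"],
        realized_counts=np.asarray(d["realized_counts"]),
        depth_per_sample=d["depth_per_sample"],
    )
    return tt
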