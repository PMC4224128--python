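"""Read preparation: fixed-length trimming and depth capping.

Mirrors the standard preparation of single-end amplicon time-series data:
every read is cut to a fixed length (130 nt by default) by taking its 5'
prefix, reads shorter than that are removed, and any sample deeper than
the cap (20,000 reads by default) is randomly subsampled without
replacement to the cap.  Subsampling uses a per-sample random substream
derived from the global seed and the sample id, so adding or removing a
sample never perturbs the reads kept in the others.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from oligodyn.synthetic import MANIFEST_COLUMNS


@dataclass
class PrepConfig:
    """Trim length (nt), per-sample depth cap (reads), and the global seed.

    ``canonical_sort`` sorts each sample's reads lexicographically before
    subsampling, making the retained multiset independent of input order.
    """

    trim_length: int = 130
    subsample_depth: int = 20_000
    seed: int = 0
    canonical_sort: bool = False

    def __post_init__(self) -> None:
        if self.trim_length < 1:
            raise ValueError("trim_length must be >= 1")
        if self.subsample_depth < 1:
            raise ValueError("subsample_depth must be >= 1")


@dataclass
class ReadSet:
    """Equal-length reads grouped by sample."""

    reads: dict[str, list[str]]
    length: int

    def __post_init__(self) -> None:
        for sid, seqs in self.reads.items():
            for s in seqs:
                if len(s) != self.length:
                    raise ValueError(
                        f"sample {sid}: read of length {len(s)} != {self.length}"
                    )

    @property
    def n_reads(self) -> int:
        return sum(len(v) for v in self.reads.values())

    @property
    def sample_ids(self) -> list[str]:
        return list(self.reads)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a sample manifest TSV.

    Columns: sample_id, subject_id, day, path, n_reads.  Paths are kept as
    written; callers resolve them relative to the manifest's directory.
    """
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns {missing}")
    if df["sample_id"].duplicated().any():
        dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
        raise ValueError(f"duplicate sample_id in manifest: {dupes}")
    if (df["day"] < 0).any():
        raise ValueError("manifest contains negative day values")
    return df


def _sniff_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ValueError(f"{path}: unrecognized sequence format")
    return "empty"


def load_sample_reads(path: str | Path) -> list[str]:
    """Parse one FASTA/FASTQ file (auto-detected) into uppercase sequences."""
    path = Path(path)
    fmt = _sniff_format(path)
    if fmt == "empty":
        warnings.warn(f"{path}: empty read file", stacklevel=2)
        return []
    seqs = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            s = str(rec.seq).upper()
            if not s:
                raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
            seqs.append(s)
    except ValueError as exc:
        raise ValueError(f"malformed record in {path}: {exc}") from exc
    return seqs


def load_reads(manifest: pd.DataFrame, base_dir: str | Path) -> dict[str, list[str]]:
    """Load every manifest sample's reads, keyed by sample id."""
    base = Path(base_dir)
    out: dict[str, list[str]] = {}
    for row in manifest.itertuples():
        p = Path(row.path)
        out[row.sample_id] = load_sample_reads(p if p.is_absolute() else base / p)
    return out


def trim_and_filter(
    raw_reads: dict[str, list[str]], config: PrepConfig
) -> tuple[ReadSet, pd.DataFrame]:
    """Trim every read to the 5' prefix of ``trim_length`` nt; drop shorter reads.

    Returns the uniform-length :class:`ReadSet` and a per-sample report
    with retained and dropped counts (retained + dropped = input).
    """
    L = config.trim_length
    trimmed: dict[str, list[str]] = {}
    rows = []
    for sid, seqs in raw_reads.items():
        kept = [s[:L] for s in seqs if len(s) >= L]
        trimmed[sid] = kept
        rows.append((sid, len(seqs), len(kept), len(seqs) - len(kept)))
    report = pd.DataFrame(rows, columns=["sample_id", "n_input", "n_retained", "n_dropped"])
    return ReadSet(trimmed, L), report


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # derived substream: global seed + CRC32 of the sample id, so each
    # sample's subsampling is independent of the manifest's other samples
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(sample_id.encode()),))
    )


def subsample(readset: ReadSet, config: PrepConfig) -> ReadSet:
    """Cap each sample at ``subsample_depth`` reads, uniformly without replacement.

    Samples at or below the cap pass through untouched.  Deterministic for
    a fixed seed; retained reads keep their input order.
    """
    out: dict[str, list[str]] = {}
    for sid, seqs in readset.reads.items():
        pool = sorted(seqs) if config.canonical_sort else seqs
        if len(pool) <= config.subsample_depth:
            out[sid] = list(pool)
            continue
        rng = _sample_rng(config.seed, sid)
        idx = rng.choice(len(pool), size=config.subsample_depth, replace=False)
        idx.sort()
        out[sid] = [pool[i] for i in idx]
    return ReadSet(out, readset.length)


def prepare(
    manifest: pd.DataFrame, base_dir: str | Path, config: PrepConfig
) -> tuple[ReadSet, pd.DataFrame]:
    """Load, trim, and subsample all manifest samples in one call."""
    raw = load_reads(manifest, base_dir)
    trimmed, report = trim_and_filter(raw, config)
    capped = subsample(trimmed, config)
    report = report.assign(
        n_final=[len(capped.reads[s]) for s in report["sample_id"]]
    )
    return capped, report


def write_readset(
    readset: ReadSet, manifest: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Serialize a prepared ReadSet as one FASTA per sample plus an updated manifest."""
    out_dir = Path(out_dir)
    reads_dir = out_dir / "prepared"
    reads_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for row in manifest.itertuples():
        seqs = readset.reads.get(row.sample_id, [])
        rel = Path("prepared") / f"{row.sample_id}.fasta"
        with open(out_dir / rel, "w") as fh:
            for i, s in enumerate(seqs, start=1):
                fh.write(f">{row.sample_id}_r{i:06d}\n{s}\n")
        rows.append((row.sample_id, row.subject_id, row.day, str(rel), len(seqs)))
    path = out_dir / "manifest.prepared.tsv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(path, sep="\t", index=False)
    return path
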