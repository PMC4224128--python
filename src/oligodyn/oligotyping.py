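"""Shannon-entropy oligotyping: the decomposition core.

Reads of one taxonomic family (all the same length) are partitioned by
their bases at a small set of high-entropy alignment columns.  The
initial partition uses the positions with the highest column entropy
(two by default); groups whose internal entropy still exceeds a stop
threshold are split further by appending up to five additional positions
per pass, recomputed inside each group, until every group is internally
quiet.  Error-driven groups are removed by the minimum substantive
abundance filter: an oligotype survives only when its most abundant
unique member sequence reaches a read-count floor (500 by default).

Column entropy is the plain Shannon entropy in bits over the 5-letter
alphabet {A, C, G, T, N}:

    H(i) = - sum_b  p_b(i) * log2 p_b(i)

with p_b(i) the frequency of symbol b in column i; monomorphic columns
score zero and H is bounded by log2(5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from oligodyn._seq import N_SYMBOLS, encode_many


@dataclass
class DecompositionConfig:
    """Tuning knobs of the decomposition.

    n_initial_components:
        Number of highest-entropy positions used for the first partition.
    max_new_positions_per_iteration:
        Cap on positions appended to a group per refinement pass (1–5).
    entropy_stop_threshold:
        A group is split further while its internal maximum column
        entropy exceeds this value (bits).  The default, 0.2 bits,
        separates genuine single-nucleotide variants cleanly from
        sequencing error at error rates around 0.1% per base.
    min_substantive_abundance:
        Read-count floor (M) on an oligotype's most abundant unique
        member sequence; the comparison is inclusive (>= M survives).
    max_iterations:
        Refinement pass limit; hitting it sets a warning flag.
    """

    n_initial_components: int = 2
    max_new_positions_per_iteration: int = 5
    entropy_stop_threshold: float = 0.2
    min_substantive_abundance: int = 500
    max_iterations: int = 20

    def __post_init__(self) -> None:
        if not (1 <= self.max_new_positions_per_iteration <= 5):
            raise ValueError("max_new_positions_per_iteration must be in 1..5")
        if self.min_substantive_abundance < 1:
            raise ValueError("min_substantive_abundance must be >= 1")
        if self.n_initial_components < 1:
            raise ValueError("n_initial_components must be >= 1")
        if self.entropy_stop_threshold < 0:
            raise ValueError("entropy_stop_threshold must be >= 0")


@dataclass
class Oligotype:
    """One oligotype: unique member sequences agreeing at the component positions."""

    family: str
    component_positions: tuple[int, ...]  # 0-based, sorted; reported 1-based
    label: str
    members: list[str]
    member_counts: np.ndarray
    member_sample_counts: pd.DataFrame  # rows align with members, columns are samples

    def __post_init__(self) -> None:
        if len(self.label) != len(self.component_positions):
            raise ValueError("label length must equal number of component positions")
        for m in self.members:
            got = "".join(m[p] for p in self.component_positions)
            if got != self.label:
                raise ValueError(f"member disagrees with label {self.label!r} at components")

    @property
    def positions_1based(self) -> tuple[int, ...]:
        return tuple(p + 1 for p in self.component_positions)

    @property
    def representative(self) -> str:
        """Most abundant unique member sequence (first on ties)."""
        return self.members[int(np.argmax(self.member_counts))]

    @property
    def max_member_count(self) -> int:
        return int(self.member_counts.max())

    @property
    def total_count(self) -> int:
        return int(self.member_counts.sum())

    @property
    def sample_counts(self) -> pd.Series:
        return self.member_sample_counts.sum(axis=0)


@dataclass
class OligotypeSet:
    """All oligotypes of one family, plus reads discarded by filtering."""

    family: str
    oligotypes: list[Oligotype]
    discarded_read_count: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        keys = [(o.component_positions, o.label) for o in self.oligotypes]
        if len(set(keys)) != len(keys):
            raise ValueError("oligotypes must have pairwise distinct (positions, label)")


def collapse_reads(
    reads_by_sample: dict[str, Sequence[str]]
) -> tuple[list[str], pd.DataFrame]:
    """Collapse reads to unique sequences with a per-sample count table."""
    seqs: list[str] = []
    sample_ids: list[str] = []
    for sid, reads in reads_by_sample.items():
        seqs.extend(reads)
        sample_ids.extend([sid] * len(reads))
    if not seqs:
        raise ValueError("no reads to collapse")
    df = pd.crosstab(pd.Series(seqs, name="seq"), pd.Series(sample_ids, name="sample"))
    df = df.reindex(columns=list(reads_by_sample), fill_value=0)
    return list(df.index), df.reset_index(drop=True)


def _entropy_from_codes(codes: np.ndarray, weights: np.ndarray) -> np.ndarray:
    freq = np.zeros((N_SYMBOLS, codes.shape[1]))
    for s in range(N_SYMBOLS):
        freq[s] = weights @ (codes == s)
    total = freq.sum(axis=0)
    p = freq / total
    h = -np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0).sum(axis=0)
    return h


def column_entropy(
    reads: Sequence[str], counts: Sequence[int] | None = None
) -> np.ndarray:
    """Per-column Shannon entropy (bits) of equal-length reads.

    ``counts`` weights each sequence (for collapsed unique reads); omitted,
    every read counts once.
    """
    if len(reads) == 0:
        raise ValueError("cannot compute entropy of an empty read set")
    codes = encode_many(list(reads))
    w = np.ones(len(reads)) if counts is None else np.asarray(counts, dtype=float)
    if (w < 0).any() or w.sum() == 0:
        raise ValueError("counts must be non-negative with positive total")
    return _entropy_from_codes(codes, w)


def _rank_positions(entropy: np.ndarray) -> np.ndarray:
    """Position indices ordered by decreasing entropy, ties to the lower index."""
    return np.argsort(-entropy, kind="stable")


def _partition(
    family: str,
    positions: tuple[int, ...],
    members: list[str],
    member_counts: np.ndarray,
    sample_counts: pd.DataFrame,
) -> list[Oligotype]:
    groups: dict[str, list[int]] = {}
    for i, seq in enumerate(members):
        label = "".join(seq[p] for p in positions)
        groups.setdefault(label, []).append(i)
    out = []
    for label in sorted(groups):
        idx = groups[label]
        out.append(
            Oligotype(
                family=family,
                component_positions=positions,
                label=label,
                members=[members[i] for i in idx],
                member_counts=member_counts[idx],
                member_sample_counts=sample_counts.iloc[idx].reset_index(drop=True),
            )
        )
    return out


def initial_decompose(
    reads_by_sample: dict[str, Sequence[str]],
    profile: np.ndarray,
    config: DecompositionConfig,
    family: str = "family",
) -> OligotypeSet:
    """First partition: group reads by their bases at the top-entropy positions.

    The ``n_initial_components`` positions of highest entropy are selected
    (ties to the lower index).  With fewer polymorphic positions than
    requested, the polymorphic ones are used with a warning; a fully
    monomorphic family degenerates to a single group.
    """
    members, sample_counts = collapse_reads(reads_by_sample)
    member_counts = sample_counts.sum(axis=1).to_numpy()
    n_init = config.n_initial_components
    polymorphic = np.flatnonzero(profile > 0)
    if polymorphic.size == 0:
        positions = tuple(range(min(n_init, len(profile))))
    elif polymorphic.size < n_init:
        warnings.warn(
            f"{family}: only {polymorphic.size} polymorphic positions for "
            f"{n_init} requested components",
            stacklevel=2,
        )
        positions = tuple(sorted(int(p) for p in polymorphic))
    else:
        top = _rank_positions(profile)[:n_init]
        positions = tuple(sorted(int(p) for p in top))
    return OligotypeSet(
        family, _partition(family, positions, members, member_counts, sample_counts)
    )


def refine(oligoset: OligotypeSet, config: DecompositionConfig) -> OligotypeSet:
    """Split groups on recomputed internal entropy until quiet or iteration cap.

    Each pass appends to every noisy group (internal max entropy above the
    stop threshold) up to ``max_new_positions_per_iteration`` of its
    highest-entropy internal positions and re-partitions it.  Refinement
    only ever splits groups.  Non-convergence at ``max_iterations`` returns
    the current state with ``converged=False``.
    """
    current = list(oligoset.oligotypes)
    converged = False
    for _ in range(config.max_iterations):
        nxt: list[Oligotype] = []
        changed = False
        for olig in current:
            if len(olig.members) <= 1:
                nxt.append(olig)
                continue
            codes = encode_many(olig.members)
            h = _entropy_from_codes(codes, olig.member_counts.astype(float))
            if h.max() <= config.entropy_stop_threshold:
                nxt.append(olig)
                continue
            candidates = [
                int(p)
                for p in _rank_positions(h)
                if h[p] > config.entropy_stop_threshold
                and int(p) not in olig.component_positions
            ][: config.max_new_positions_per_iteration]
            if not candidates:
                nxt.append(olig)
                continue
            new_positions = tuple(sorted(set(olig.component_positions) | set(candidates)))
            nxt.extend(
                _partition(
                    olig.family,
                    new_positions,
                    olig.members,
                    olig.member_counts,
                    olig.member_sample_counts,
                )
            )
            changed = True
        current = nxt
        if not changed:
            converged = True
            break
    else:
        converged = not any(
            len(o.members) > 1
            and _entropy_from_codes(
                encode_many(o.members), o.member_counts.astype(float)
            ).max()
            > config.entropy_stop_threshold
            for o in current
        )
    if not converged:
        warnings.warn(
            f"{oligoset.family}: refinement did not converge in "
            f"{config.max_iterations} iterations",
            stacklevel=2,
        )
    return OligotypeSet(
        oligoset.family, current, oligoset.discarded_read_count, converged
    )


def filter_min_substantive_abundance(
    oligoset: OligotypeSet, config: DecompositionConfig
) -> OligotypeSet:
    """Drop oligotypes whose most abundant unique member is below M reads.

    The comparison is inclusive: a maximum member count equal to M
    survives.  Reads of removed oligotypes are added to the set's
    ``discarded_read_count``.
    """
    kept, discarded = [], oligoset.discarded_read_count
    for olig in oligoset.oligotypes:
        if olig.max_member_count >= config.min_substantive_abundance:
            kept.append(olig)
        else:
            discarded += olig.total_count
    return OligotypeSet(oligoset.family, kept, discarded, oligoset.converged)


def decompose_family(
    family: str,
    reads_by_sample: dict[str, Sequence[str]],
    config: DecompositionConfig | None = None,
) -> OligotypeSet:
    """Full decomposition of one family: entropy, initial split, refine, M-filter."""
    config = config or DecompositionConfig()
    members, sample_counts = collapse_reads(reads_by_sample)
    profile = _entropy_from_codes(
        encode_many(members), sample_counts.sum(axis=1).to_numpy(dtype=float)
    )
    oligoset = initial_decompose(reads_by_sample, profile, config, family=family)
    oligoset = refine(oligoset, config)
    return filter_min_substantive_abundance(oligoset, config)


def oligotype_ids(oligoset: OligotypeSet) -> list[tuple[str, Oligotype]]:
    """Family-qualified ids by descending total abundance: ``Family_oligo_001``."""
    ranked = sorted(
        oligoset.oligotypes, key=lambda o: (-o.total_count, o.label, o.component_positions)
    )
    return [(f"{oligoset.family}_oligo_{i:03d}", o) for i, o in enumerate(ranked, start=1)]


def build_counts_matrix(
    oligosets: Sequence[OligotypeSet], manifest: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate per-family observation matrices into one counts table.

    Rows are family-qualified oligotype ids, columns every manifest sample
    (zero column where an oligotype was never seen); cell values are read
    counts.
    """
    sample_ids = list(manifest["sample_id"])
    rows = {}
    for oset in oligosets:
        for oid, olig in oligotype_ids(oset):
            if oid in rows:
                raise ValueError(f"duplicate oligotype id {oid}")
            rows[oid] = olig.sample_counts.reindex(sample_ids, fill_value=0)
    if not rows:
        return pd.DataFrame(columns=sample_ids, dtype=int)
    return pd.DataFrame(rows).T.astype(int)[sample_ids]


def normalize_percent(counts: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Counts to percent of each sample's retained total.

    Returns the percent matrix and the ids of all-zero samples, which are
    left at zero rather than divided.
    """
    totals = counts.sum(axis=0)
    zero_cols = [str(c) for c in totals.index[totals == 0]]
    safe = totals.replace(0, 1)
    return counts.div(safe, axis=1) * 100.0, zero_cols


def oligotype_report(oligosets: Sequence[OligotypeSet]) -> pd.DataFrame:
    """Tabular summary: id, family, 1-based components, label, representative, counts."""
    rows = []
    for oset in oligosets:
        for oid, o in oligotype_ids(oset):
            rows.append(
                {
                    "oligotype_id": oid,
                    "family": o.family,
                    "component_positions": ",".join(str(p) for p in o.positions_1based),
                    "label": o.label,
                    "representative": o.representative,
                    "total_count": o.total_count,
                    "max_member_count": o.max_member_count,
                    "n_unique_members": len(o.members),
                }
            )
    return pd.DataFrame(rows)
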