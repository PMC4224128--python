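"""Reference-based taxonomy assignment and genome identity scans.

Family-level read classification is a nearest-reference search: each read
is compared, ungapped, against every window of every reference sequence,
and inherits the family of the best-identity hit (ties count only when
all tied references agree on the family).  Species-level assignment of
oligotype representatives works the same way but reports every reference
attaining the maximal identity and applies an identity floor (90% by
default) below which the query is left unassigned.  Genome scans use
local alignment with unit match/mismatch/gap costs on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from oligodyn._seq import encode, encode_many, reverse_complement
from oligodyn.panel import PanelEntry, ReferencePanel


@dataclass
class TaxonomyConfig:
    """Identity floor (%) below which a query stays unassigned."""

    identity_floor: float = 90.0

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_floor <= 100.0):
            raise ValueError("identity_floor must be in (0, 100]")


@dataclass
class TaxonAssignment:
    query_id: str
    best_hits: list[PanelEntry] = field(default_factory=list)
    percent_identity: float = 0.0
    status: str = "unassigned"  # "assigned" | "unassigned"


def _identity_matrix(read_codes: np.ndarray, panel: ReferencePanel) -> np.ndarray:
    """Best ungapped sliding-window identity (%) of each read against each reference.

    read_codes: (n, L) uint8.  Returns (n, n_refs) float64.
    """
    n, L = read_codes.shape
    best = np.zeros((n, len(panel)), dtype=np.float64)
    for r, entry in enumerate(panel):
        ref = encode(entry.sequence)
        if len(ref) < L:
            raise ValueError(
                f"reference {entry.name} shorter ({len(ref)}) than reads ({L})"
            )
        best_matches = np.zeros(n, dtype=np.int32)
        for off in range(len(ref) - L + 1):
            window = ref[off : off + L]
            m = (read_codes == window).sum(axis=1).astype(np.int32)
            np.maximum(best_matches, m, out=best_matches)
        best[:, r] = 100.0 * best_matches / L
    return best


def classify_reads_family(reads: list[str], panel: ReferencePanel) -> list[str | None]:
    """Classify many same-length reads to family; None where tied hits disagree."""
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    if not reads:
        return []
    codes = encode_many(reads)
    ident = _identity_matrix(codes, panel)
    families = np.array([e.family for e in panel])
    out: list[str | None] = []
    for i in range(len(reads)):
        row = ident[i]
        tied = families[row >= row.max() - 1e-9]
        out.append(tied[0] if len(set(tied)) == 1 else None)
    return out


def classify_read_family(read: str, panel: ReferencePanel) -> str | None:
    """Family of the best ungapped sliding-window hit, or None on a family tie."""
    return classify_reads_family([read], panel)[0]


def assign_oligotype_taxonomy(
    representative: str,
    panel: ReferencePanel,
    config: TaxonomyConfig | None = None,
    query_id: str = "query",
) -> TaxonAssignment:
    """Assign taxonomy to an oligotype representative by best reference identity.

    All references attaining the maximal identity are reported together
    (a representative identical to several species' references lists them
    all); below the identity floor the status is "unassigned".
    """
    config = config or TaxonomyConfig()
    if len(panel) == 0:
        raise ValueError("empty reference panel")
    ident = _identity_matrix(encode(representative)[None, :], panel)[0]
    top = float(ident.max())
    hits = [e for e, v in zip(panel, ident) if v >= top - 1e-9]
    if top < config.identity_floor:
        return TaxonAssignment(query_id, hits, top, "unassigned")
    return TaxonAssignment(query_id, hits, top, "assigned")


def best_window_identity(a: str, b: str) -> float:
    """Best ungapped sliding-window identity (%) of the shorter sequence in the longer."""
    query, ref = (a, b) if len(a) <= len(b) else (b, a)
    qc = encode(query)
    rc = encode(ref)
    L = len(qc)
    best = 0
    for off in range(len(rc) - L + 1):
        m = int((qc == rc[off : off + L]).sum())
        if m > best:
            best = m
    return 100.0 * best / L


def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -1
    return aligner


def genome_identity_scan(query: str, genomes: dict[str, str]) -> dict[str, float]:
    """Maximum local-alignment identity (%) of a query against each genome.

    Both the genome and its reverse complement are scanned; identity is
    matches over aligned columns (gaps included) of the highest-scoring
    local alignment.
    """
    aligner = _local_aligner()
    out: dict[str, float] = {}
    for name, genome in genomes.items():
        if len(query) >= len(genome):
            raise ValueError(f"query not shorter than genome {name!r}")
        best = 0.0
        for target in (genome, reverse_complement(genome)):
            alns = aligner.align(target, query)
            if len(alns) == 0:
                continue
            aln = alns[0]
            counts = aln.counts()
            length = counts.identities + counts.mismatches + counts.gaps
            if length:
                best = max(best, 100.0 * counts.identities / length)
        out[name] = best
    return out
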