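"""Genotypes as explicit promoter (URR) sequences and their regulatory networks.

A genotype is n upstream regulatory regions of length L, a fixed vector of
activator/repressor signs, and a fixed binary initial expression state.  The
interaction matrix w is built by scanning every overlapping 8-mer window of
every URR against every TF's specificity table (forward strand only) and
summing kappa per (gene, TF) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from . import _kernels, landscape as ls
from .errors import (
    ConfigurationError,
    IncompatibleParentsError,
    InvalidParameterError,
    InvalidSequenceError,
)

_CODE_TO_BASE = np.frombuffer(ls.ALPHABET.encode("ascii"), dtype=np.uint8)


@dataclass
class Genotype:
    """n URR strings plus fixed TF signs and initial expression state."""

    urrs: Tuple[str, ...]
    tf_signs: np.ndarray  # in {-1, +1}, length n
    initial_state: np.ndarray  # in {0, 1}, length n

    def __post_init__(self) -> None:
        self.urrs = tuple(self.urrs)
        self.tf_signs = np.asarray(self.tf_signs, dtype=float)
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        n = len(self.urrs)
        if self.tf_signs.shape != (n,) or self.initial_state.shape != (n,):
            raise ConfigurationError("signs/initial state must have one entry per gene")
        lengths = {len(u) for u in self.urrs}
        if len(lengths) > 1:
            raise InvalidSequenceError("all URRs must share the same length")

    @property
    def n(self) -> int:
        return len(self.urrs)

    @property
    def L(self) -> int:
        return len(self.urrs[0])

    @property
    def genome_length(self) -> int:
        return self.n * self.L


@dataclass
class SiteAnnotation:
    """One TFBS occurrence: TF ``tf`` bound at ``offset`` in gene ``gene``'s URR."""

    gene: int
    tf: int
    offset: int
    kappa: float


@dataclass
class RegulatoryNetwork:
    """Interaction matrix w (n x n) plus the site annotations behind it."""

    w: np.ndarray
    sites: List[SiteAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ConfigurationError("w must be a square matrix")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def site_counts(self) -> np.ndarray:
        """(n, n) integer matrix of TFBS counts per (gene, TF) input."""
        counts = np.zeros_like(self.w, dtype=int)
        for s in self.sites:
            counts[s.gene, s.tf] += 1
        return counts


@dataclass
class PointMutation:
    gene: int
    position: int
    old_base: str
    new_base: str


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def random_urr(L: int, rng: np.random.Generator) -> str:
    """Uniform random DNA string of length L (>= 8)."""
    if L < ls.K:
        raise InvalidParameterError(f"URR length must be >= {ls.K}, got {L}")
    codes = rng.integers(0, 4, size=L)
    return _CODE_TO_BASE[codes].tobytes().decode("ascii")


def random_genotype(n: int, L: int, rng: np.random.Generator) -> Genotype:
    """Random URRs, random +-1 signs, random 0/1 initial state."""
    urrs = tuple(random_urr(L, rng) for _ in range(n))
    signs = rng.choice([-1.0, 1.0], size=n)
    state = rng.integers(0, 2, size=n).astype(float)
    return Genotype(urrs=urrs, tf_signs=signs, initial_state=state)


def scan_urr(
    urr: str, tables: Sequence[ls.SpecificityTable], gene: int = 0
) -> List[SiteAnnotation]:
    """Annotate every (window, TF) pair with kappa > 0 in one URR.

    All L-7 overlapping forward-strand windows are tested against every
    table; overlapping and nested sites are all reported.
    """
    idx = ls.window_indices(urr)
    stack = ls.kappa_stack(tables)
    kap = stack[:, idx]  # (n_tf, L-7)
    tf_ix, off_ix = np.nonzero(kap)
    return [
        SiteAnnotation(gene=gene, tf=int(j), offset=int(o), kappa=float(kap[j, o]))
        for j, o in zip(tf_ix, off_ix)
    ]


def build_network(
    genotype: Genotype, tables: Sequence[ls.SpecificityTable]
) -> RegulatoryNetwork:
    """w_ij = sum of kappa over TF j's annotated sites in gene i's URR."""
    n = genotype.n
    if len(tables) != n:
        raise ConfigurationError(
            f"need one table per gene: {len(tables)} tables, {n} genes"
        )
    stack = ls.kappa_stack(tables)
    w = np.zeros((n, n))
    sites: List[SiteAnnotation] = []
    for i, urr in enumerate(genotype.urrs):
        idx = ls.window_indices(urr)
        kap = stack[:, idx]
        w[i] = _row_sum(stack, idx, kap)
        tf_ix, off_ix = np.nonzero(kap)
        sites.extend(
            SiteAnnotation(gene=i, tf=int(j), offset=int(o), kappa=float(kap[j, o]))
            for j, o in zip(tf_ix, off_ix)
        )
    return RegulatoryNetwork(w=w, sites=sites)


def _row_sum(stack: np.ndarray, idx: np.ndarray, kap=None) -> np.ndarray:
    """One w row; the compiled and NumPy paths must stay interchangeable."""
    if _kernels.HAVE_NUMBA:
        return _kernels.row_sums(stack, idx)
    if kap is None:
        kap = stack[:, idx]
    return kap.sum(axis=1)


def build_w(genotype: Genotype, tables: Sequence[ls.SpecificityTable]) -> np.ndarray:
    """Fast path: the interaction matrix only, no site annotations."""
    stack = ls.kappa_stack(tables)
    n = genotype.n
    w = np.empty((n, n))
    for i, urr in enumerate(genotype.urrs):
        w[i] = _row_sum(stack, ls.window_indices(urr))
    return w


def connectivity(network: RegulatoryNetwork | np.ndarray) -> float:
    """Fraction of nonzero entries in w."""
    w = network.w if isinstance(network, RegulatoryNetwork) else np.asarray(network)
    return float(np.count_nonzero(w)) / w.size


# ---------------------------------------------------------------------------
# genetic operators
# ---------------------------------------------------------------------------


def point_mutate(
    genotype: Genotype, rate_per_bp: float, rng: np.random.Generator
) -> Tuple[Genotype, List[PointMutation]]:
    """Independent per-base substitution at ``rate_per_bp``; uniform new base."""
    if not 0.0 <= rate_per_bp <= 1.0:
        raise InvalidParameterError("mutation rate must lie in [0, 1]")
    mutations: List[PointMutation] = []
    if rate_per_bp == 0.0:
        return genotype, mutations
    new_urrs = list(genotype.urrs)
    L = genotype.L
    flat_hits = np.flatnonzero(rng.random(genotype.n * L) < rate_per_bp)
    if flat_hits.size:
        # uniform over the 3 alternative bases, drawn in one batch
        draws = rng.integers(0, 3, size=flat_hits.size)
        bufs: dict = {}
        for k, pos_flat in enumerate(flat_hits):
            g, pos = divmod(int(pos_flat), L)
            buf = bufs.get(g)
            if buf is None:
                buf = bufs[g] = bytearray(new_urrs[g], "ascii")
            old = chr(buf[pos])
            new = ls.ALPHABET[(ls.ALPHABET.index(old) + 1 + draws[k]) % 4]
            buf[pos] = ord(new)
            mutations.append(
                PointMutation(gene=g, position=pos, old_base=old, new_base=new)
            )
        for g, buf in bufs.items():
            new_urrs[g] = buf.decode("ascii")
    mutated = Genotype(
        urrs=tuple(new_urrs),
        tf_signs=genotype.tf_signs,
        initial_state=genotype.initial_state,
    )
    return mutated, mutations


def apply_mutation(genotype: Genotype, mutation: PointMutation) -> Genotype:
    """Return a copy of the genotype with one substitution applied."""
    urr = genotype.urrs[mutation.gene]
    if urr[mutation.position] != mutation.old_base:
        raise InvalidSequenceError("mutation old_base does not match the genotype")
    new_urr = (
        urr[: mutation.position] + mutation.new_base + urr[mutation.position + 1 :]
    )
    urrs = list(genotype.urrs)
    urrs[mutation.gene] = new_urr
    return Genotype(
        urrs=tuple(urrs),
        tf_signs=genotype.tf_signs,
        initial_state=genotype.initial_state,
    )


def recombine(
    parent_a: Genotype, parent_b: Genotype, rng: np.random.Generator
) -> Genotype:
    """Per-URR sexual reproduction: each offspring URR comes from one parent.

    No recombination occurs within a promoter region.
    """
    if (
        parent_a.n != parent_b.n
        or parent_a.L != parent_b.L
        or not np.array_equal(parent_a.tf_signs, parent_b.tf_signs)
        or not np.array_equal(parent_a.initial_state, parent_b.initial_state)
    ):
        raise IncompatibleParentsError("parents must share n, L, signs, initial state")
    picks = rng.random(parent_a.n) < 0.5
    urrs = tuple(
        parent_a.urrs[g] if picks[g] else parent_b.urrs[g] for g in range(parent_a.n)
    )
    return Genotype(
        urrs=urrs, tf_signs=parent_a.tf_signs, initial_state=parent_a.initial_state
    )


# ---------------------------------------------------------------------------
# descriptive measures
# ---------------------------------------------------------------------------


def tfbs_free_fraction(genotype: Genotype, network: RegulatoryNetwork) -> float:
    """Fraction of genome positions not covered by any site's 8-bp footprint."""
    covered = np.zeros((genotype.n, genotype.L), dtype=bool)
    for s in network.sites:
        covered[s.gene, s.offset : s.offset + ls.K] = True
    return 1.0 - float(covered.sum()) / genotype.genome_length


def redundancy_count(network: RegulatoryNetwork) -> int:
    """Total sites in excess of one per realized (gene, TF) input."""
    counts = network.site_counts()
    return int(np.maximum(counts - 1, 0).sum())


# ---------------------------------------------------------------------------
# I/O: FASTA URRs + JSON metadata sidecar
# ---------------------------------------------------------------------------


def write_genotype(genotype: Genotype, fasta_path, meta_path=None) -> None:
    """Write URRs as FASTA (records gene0..gene<n-1>) plus a JSON sidecar
    with the fixed signs and initial state."""
    import json
    from pathlib import Path

    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    fasta_path = Path(fasta_path)
    records = [
        SeqRecord(Seq(urr), id=f"gene{i}", description="")
        for i, urr in enumerate(genotype.urrs)
    ]
    seqio_write(records, str(fasta_path), "fasta")
    if meta_path is None:
        meta_path = fasta_path.with_suffix(".json")
    meta = {
        "n": genotype.n,
        "L": genotype.L,
        "tf_signs": [int(v) for v in genotype.tf_signs],
        "initial_state": [int(v) for v in genotype.initial_state],
    }
    Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_genotype(fasta_path, meta_path=None) -> Genotype:
    """Inverse of :func:`write_genotype`."""
    import json
    from pathlib import Path

    from Bio.SeqIO import parse as seqio_parse

    fasta_path = Path(fasta_path)
    if meta_path is None:
        meta_path = fasta_path.with_suffix(".json")
    meta = json.loads(Path(meta_path).read_text())
    records = {rec.id: str(rec.seq) for rec in seqio_parse(str(fasta_path), "fasta")}
    urrs = tuple(records[f"gene{i}"] for i in range(meta["n"]))
    return Genotype(
        urrs=urrs,
        tf_signs=np.asarray(meta["tf_signs"], dtype=float),
        initial_state=np.asarray(meta["initial_state"], dtype=float),
    )
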