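"""Per-TF binding landscapes over all 4^8 = 65,536 DNA 8-mers.

A landscape assigns every 8-mer a raw score ``epsilon`` (lower = stronger
binding), a normalized score ``epsilon_prime`` in [0, 1] (1 at the consensus
site, 0 at the worst site), and a sparse specificity ``kappa`` in {0} U
[gamma, 1].  The binder set is fixed by the normalized threshold
``EPRIME_OPT = 0.209`` and is therefore independent of the specificity gap
``gamma``; gamma only reshapes kappa values on that set.

Synthetic landscapes are built from an additive per-position energy matrix
plus an optional pairwise epistatic perturbation, then monotonically rescaled
so that the binder count at the threshold is hit exactly.  This preserves the
correlated mutational neighborhoods (stronger sites tend to have more binding
single-point mutants) that the downstream conservation statistics rely on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Sequence

import numpy as np

from . import _kernels
from .errors import (
    DegenerateLandscapeError,
    InvalidParameterError,
    InvalidSequenceError,
    LandscapeFormatError,
    NotABinderError,
)

ALPHABET = "ACGT"
K = 8
N_KMERS = 4 ** K  # 65,536
EPRIME_OPT = 0.209
BINDER_RANGE = (60, 900)

_BASE_TO_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _BASE_TO_CODE[ord(_b)] = _i
# powers of 4, leftmost base most significant
_POW = 4 ** np.arange(K - 1, -1, -1, dtype=np.int64)


def encode_sequence(seq: str) -> np.ndarray:
    """Map a DNA string to an int array of base codes (A=0, C=1, G=2, T=3)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = _BASE_TO_CODE[raw]
    if (codes < 0).any():
        bad = seq[int(np.argmax(codes < 0))]
        raise InvalidSequenceError(f"invalid base {bad!r} in sequence")
    return codes


def kmer_to_index(kmer: str) -> int:
    if len(kmer) != K:
        raise InvalidSequenceError(f"expected an 8-mer, got length {len(kmer)}")
    return int(encode_sequence(kmer) @ _POW)


def index_to_kmer(index: int) -> str:
    if not 0 <= index < N_KMERS:
        raise InvalidParameterError(f"8-mer index {index} out of range")
    chars = []
    for p in _POW:
        chars.append(ALPHABET[(index // p) % 4])
    return "".join(chars)


def all_kmers() -> List[str]:
    """All 65,536 8-mers in index (lexicographic) order."""
    return [index_to_kmer(i) for i in range(N_KMERS)]


def window_indices(seq: str) -> np.ndarray:
    """8-mer indices of all len(seq) - 7 overlapping windows, left to right."""
    codes = encode_sequence(seq)
    if codes.size < K:
        raise InvalidSequenceError("sequence shorter than 8 bp")
    if _kernels.HAVE_NUMBA:
        return _kernels.scan_codes(codes)
    m = codes.size - K + 1
    idx = codes[:m] * _POW[0]
    for k in range(1, K):
        idx += codes[k : k + m] * _POW[k]
    return idx


def mutant_indices(index: int) -> np.ndarray:
    """Indices of the 24 single-point mutants of the 8-mer with this index."""
    out = np.empty(24, dtype=np.int64)
    k = 0
    for pos in range(K):
        p = int(_POW[pos])
        old = (index // p) % 4
        for new in range(4):
            if new != old:
                out[k] = index + (new - old) * p
                k += 1
    return out


def single_point_mutants(site: str) -> set:
    """The 24 sequences at Hamming distance exactly 1 from an 8-mer."""
    idx = kmer_to_index(site)
    return {index_to_kmer(int(i)) for i in mutant_indices(idx)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RawLandscape:
    """Raw scores epsilon for every 8-mer; lower means stronger binding."""

    tf_id: str
    epsilon: np.ndarray  # shape (65536,), float64, indexed by kmer index

    def __post_init__(self) -> None:
        self.epsilon = np.asarray(self.epsilon, dtype=float)
        if self.epsilon.shape != (N_KMERS,):
            raise InvalidParameterError(
                f"landscape must score all {N_KMERS} 8-mers, got {self.epsilon.shape}"
            )

    @property
    def consensus_index(self) -> int:
        """Index of the consensus 8-mer (minimum epsilon, first on ties)."""
        return int(np.argmin(self.epsilon))

    @property
    def consensus(self) -> str:
        return index_to_kmer(self.consensus_index)

    def score(self, kmer: str) -> float:
        return float(self.epsilon[kmer_to_index(kmer)])


@dataclass
class NormalizedLandscape:
    """Normalized scores epsilon' in [0, 1]; 1 at consensus, 0 at worst site."""

    tf_id: str
    eprime: np.ndarray

    def __post_init__(self) -> None:
        self.eprime = np.asarray(self.eprime, dtype=float)
        if self.eprime.shape != (N_KMERS,):
            raise InvalidParameterError("normalized landscape has wrong size")

    def score(self, kmer: str) -> float:
        return float(self.eprime[kmer_to_index(kmer)])


@dataclass
class SpecificityTable:
    """Sparse specificity kappa over 8-mers for one TF.

    Binders carry kappa in [gamma, 1] (consensus exactly 1); all other 8-mers
    have kappa = 0.  ``dense`` holds the full 65,536-vector used by the fast
    scanning paths; ``kappa`` is the sparse mapping view of the same data.
    """

    tf_id: str
    gamma: float
    lam: float
    dense: np.ndarray  # shape (65536,), zero off the binder set
    binder_count: int = field(init=False)

    def __post_init__(self) -> None:
        self.dense = np.asarray(self.dense, dtype=float)
        if self.dense.shape != (N_KMERS,):
            raise InvalidParameterError("specificity table has wrong size")
        self.binder_count = int(np.count_nonzero(self.dense))

    @property
    def kappa(self) -> Dict[str, float]:
        idx = np.flatnonzero(self.dense)
        return {index_to_kmer(int(i)): float(self.dense[i]) for i in idx}

    def kappa_of(self, kmer: str) -> float:
        return float(self.dense[kmer_to_index(kmer)])

    def is_binder(self, kmer: str) -> bool:
        return self.kappa_of(kmer) > 0.0

    @property
    def binder_indices(self) -> np.ndarray:
        return np.flatnonzero(self.dense)


@dataclass
class LandscapeParams:
    """Parameters of the synthetic landscape generator."""

    n_binders: int
    seed: int = 0
    eprime_opt: float = EPRIME_OPT
    additive_sd: float = 1.0
    epistasis_weight: float = 0.25
    tf_id: str = "tf"

    def __post_init__(self) -> None:
        if not 1 <= self.n_binders <= N_KMERS - 1:
            raise InvalidParameterError(
                f"n_binders must lie in [1, {N_KMERS - 1}], got {self.n_binders}"
            )
        if not 0.0 < self.eprime_opt < 1.0:
            raise InvalidParameterError("eprime_opt must lie in (0, 1)")
        if self.additive_sd <= 0:
            raise InvalidParameterError("additive_sd must be positive")
        if self.epistasis_weight < 0:
            raise InvalidParameterError("epistasis_weight must be >= 0")


@dataclass
class Landscape:
    """One TF's raw, normalized, and thresholded views, kept consistent."""

    raw: RawLandscape
    norm: NormalizedLandscape
    table: SpecificityTable

    @property
    def tf_id(self) -> str:
        return self.raw.tf_id


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _kmer_code_matrix() -> np.ndarray:
    """(65536, 8) matrix of base codes for every 8-mer, cached."""
    global _CODES
    try:
        return _CODES
    except NameError:
        idx = np.arange(N_KMERS, dtype=np.int64)
        _CODES = np.stack([(idx // p) % 4 for p in _POW], axis=1)
        return _CODES


def generate_raw_landscape(params: LandscapeParams) -> RawLandscape:
    """Draw a synthetic raw landscape calibrated to hit ``n_binders`` exactly.

    The score of each 8-mer is the sum of a per-position energy (8 x 4 matrix
    of N(0, additive_sd) deviations) and, if ``epistasis_weight > 0``, of
    pairwise position-position terms.  A final monotone (order-preserving)
    rescaling pins the ``n_binders``-th best normalized score to the
    ``eprime_opt`` threshold so the binder count is exact.
    """
    rng = np.random.default_rng(params.seed)
    codes = _kmer_code_matrix()

    pem = rng.normal(0.0, params.additive_sd, size=(K, 4))
    eps = pem[np.arange(K)[None, :], codes].sum(axis=1)

    if params.epistasis_weight > 0:
        scale = params.epistasis_weight * params.additive_sd
        for p in range(K):
            for q in range(p + 1, K):
                pair = rng.normal(0.0, scale, size=(4, 4))
                eps = eps + pair[codes[:, p], codes[:, q]]

    eps = _rescale_to_binder_count(eps, params.n_binders, params.eprime_opt)
    return RawLandscape(tf_id=params.tf_id, epsilon=eps)


def _rescale_to_binder_count(eps: np.ndarray, n_binders: int, eprime_opt: float) -> np.ndarray:
    """Monotone power-rescale of eps so #{eprime >= eprime_opt} == n_binders."""
    lo = eps.min()
    hi = eps.max()
    if hi == lo:
        raise DegenerateLandscapeError("all scores equal; cannot calibrate")
    eprime = (hi - eps) / (hi - lo)
    order = np.sort(eprime)[::-1]
    # value to pin at the threshold: n-th best (1-based); for n_binders == 1
    # the best is the consensus (== 1), so pin the runner-up just below.
    if n_binders >= 2:
        pivot = order[n_binders - 1]
        target = eprime_opt
    else:
        pivot = order[1]
        target = eprime_opt * (1.0 - 1e-9)
    if not 0.0 < pivot < 1.0:
        raise DegenerateLandscapeError("degenerate score ties at the extremes")

    margin = 1e-9 if n_binders >= 2 else -1e-9
    for _ in range(8):  # widen the margin until float round-trip is exact
        p = math.log(target * (1.0 + margin)) / math.log(pivot)
        ep_new = eprime ** p
        eps_new = hi - ep_new * (hi - lo)
        check = (hi - eps_new) / (hi - lo)
        if int(np.count_nonzero(check >= eprime_opt)) == n_binders:
            return eps_new
        margin *= 10.0
    raise DegenerateLandscapeError("could not calibrate binder count exactly")


def normalize(raw: RawLandscape) -> NormalizedLandscape:
    """Reference raw scores to the consensus: eprime in [0, 1], 1 = consensus."""
    lo = float(raw.epsilon.min())  # consensus score (strongest binding)
    hi = float(raw.epsilon.max())  # worst site
    if hi == lo:
        raise DegenerateLandscapeError("all epsilon equal; normalization undefined")
    eprime = (hi - raw.epsilon) / (hi - lo)
    return NormalizedLandscape(tf_id=raw.tf_id, eprime=eprime)


def lambda_from_gamma(gamma: float, eprime_opt: float = EPRIME_OPT) -> float:
    """Slope linked to the specificity gap so that kappa(eprime_opt) == gamma."""
    if not 0.0 < gamma < 1.0:
        raise InvalidParameterError(f"gamma must lie in (0, 1), got {gamma}")
    if not 0.0 < eprime_opt < 1.0:
        raise InvalidParameterError(f"eprime_opt must lie in (0, 1), got {eprime_opt}")
    return math.log(gamma) / (eprime_opt - 1.0)


def specificity(
    norm: NormalizedLandscape, gamma: float, eprime_opt: float = EPRIME_OPT
) -> SpecificityTable:
    """Threshold and exponentiate: kappa = exp(lam * (eprime - 1)) on binders.

    The binder set {eprime >= eprime_opt} does not depend on gamma; the
    weakest binder gets kappa == gamma and non-binders kappa == 0 (the
    "specificity gap" discontinuity).
    """
    lam = lambda_from_gamma(gamma, eprime_opt)
    dense = np.where(
        norm.eprime >= eprime_opt, np.exp(lam * (norm.eprime - 1.0)), 0.0
    )
    return SpecificityTable(tf_id=norm.tf_id, gamma=gamma, lam=lam, dense=dense)


def generate_landscape(params: LandscapeParams, gamma: float) -> Landscape:
    raw = generate_raw_landscape(params)
    norm = normalize(raw)
    table = specificity(norm, gamma, params.eprime_opt)
    return Landscape(raw=raw, norm=norm, table=table)


def generate_panel(
    n_tfs: int = 10,
    gamma: float = 0.05,
    seed: int = 0,
    eprime_opt: float = EPRIME_OPT,
    n_binders: Sequence[int] | None = None,
    additive_sd: float = 1.0,
    epistasis_weight: float = 0.25,
) -> List[Landscape]:
    """Generate the default TF panel: independently seeded landscapes with
    binder counts drawn log-uniformly in [60, 900] (unless given explicitly)."""
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(n_tfs + 1)
    if n_binders is None:
        draw_rng = np.random.default_rng(child_seeds[0])
        lo, hi = BINDER_RANGE
        n_binders = np.rint(
            np.exp(draw_rng.uniform(math.log(lo), math.log(hi), size=n_tfs))
        ).astype(int)
    elif len(n_binders) != n_tfs:
        raise InvalidParameterError("n_binders must have one entry per TF")
    panel = []
    for j in range(n_tfs):
        params = LandscapeParams(
            n_binders=int(n_binders[j]),
            seed=child_seeds[j + 1].generate_state(1)[0],
            eprime_opt=eprime_opt,
            additive_sd=additive_sd,
            epistasis_weight=epistasis_weight,
            tf_id=f"tf{j}",
        )
        panel.append(generate_landscape(params, gamma))
    return panel


def tfbs_conservation(site: str, table: SpecificityTable) -> float:
    """Fraction of the 24 single-point mutants that stay binders for this TF."""
    idx = kmer_to_index(site)
    if table.dense[idx] <= 0.0:
        raise NotABinderError(f"{site} is not a binder for {table.tf_id}")
    mut = mutant_indices(idx)
    return float(np.count_nonzero(table.dense[mut])) / 24.0


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_COLUMNS = ("kmer", "epsilon", "epsilon_prime", "kappa")


def write_landscape(landscape: Landscape, path: str | Path) -> None:
    """Write one TF's landscape as a 65,536-row TSV (full float precision)."""
    path = Path(path)
    eps = landscape.raw.epsilon
    ep = landscape.norm.eprime
    kap = landscape.table.dense
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for i in range(N_KMERS):
            fh.write(
                f"{index_to_kmer(i)}\t{eps[i]:.17g}\t{ep[i]:.17g}\t{kap[i]:.17g}\n"
            )


def read_landscape(path: str | Path, tf_id: str | None = None) -> Landscape:
    """Read a landscape TSV written by :func:`write_landscape`.

    gamma and lambda are recovered from the stored kappa/eprime columns
    (gamma = smallest positive kappa; threshold = smallest binder eprime).
    """
    path = Path(path)
    if tf_id is None:
        tf_id = path.stem
    eps = np.empty(N_KMERS)
    ep = np.empty(N_KMERS)
    kap = np.empty(N_KMERS)
    seen = np.zeros(N_KMERS, dtype=bool)
    n_rows = 0
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _COLUMNS:
            raise LandscapeFormatError(
                f"bad header {header!r}; expected columns {_COLUMNS}"
            )
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise LandscapeFormatError(f"malformed row: {line!r}")
            i = kmer_to_index(parts[0])
            if seen[i]:
                raise LandscapeFormatError(f"duplicate k-mer {parts[0]}")
            seen[i] = True
            eps[i] = float(parts[1])
            ep[i] = float(parts[2])
            kap[i] = float(parts[3])
            n_rows += 1
    if n_rows != N_KMERS:
        raise LandscapeFormatError(
            f"expected {N_KMERS} rows, found {n_rows}"
        )
    raw = RawLandscape(tf_id=tf_id, epsilon=eps)
    norm = NormalizedLandscape(tf_id=tf_id, eprime=ep)
    binders = kap > 0
    if binders.any():
        gamma = float(kap[binders].min())
        thr = float(ep[binders].min())
        lam = lambda_from_gamma(gamma, thr) if 0 < gamma < 1 and 0 < thr < 1 else 0.0
    else:
        gamma, lam = 0.0, 0.0
    table = SpecificityTable(tf_id=tf_id, gamma=gamma, lam=lam, dense=kap)
    return Landscape(raw=raw, norm=norm, table=table)


# ---------------------------------------------------------------------------
# fast multi-TF access
# ---------------------------------------------------------------------------

_STACK_CACHE: dict = {}


def kappa_stack(tables: Sequence[SpecificityTable]) -> np.ndarray:
    """(n_tf, 65536) matrix of kappa vectors, cached per table tuple.

    The cache keeps strong references to the tables, so ``id`` keys stay valid.
    """
    key = tuple(id(t) for t in tables)
    hit = _STACK_CACHE.get(key)
    if hit is not None:
        return hit[0]
    stack = np.stack([t.dense for t in tables])
    if len(_STACK_CACHE) > 32:
        _STACK_CACHE.clear()
    _STACK_CACHE[key] = (stack, tuple(tables))
    return stack


def tables_of(panel: Iterable) -> List[SpecificityTable]:
    """Accept a panel of Landscape bundles or bare tables; return the tables."""
    out = []
    for item in panel:
        out.append(item.table if isinstance(item, Landscape) else item)
    return out
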