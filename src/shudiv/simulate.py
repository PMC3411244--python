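"""Two-lineage coalescent simulation of query/subject sequence pairs.

Generates pairs of homologous DNA sequences with known per-site time to
the most recent common ancestor (TMRCA) and known mismatch positions, for
validating the shustring-based estimators.  The TMRCA process along the
sequence follows the SMC' approximation of the two-sample coalescent with
recombination: the marginal TMRCA at every site is Exp(1) in coalescent
units, recombination breakpoints arise at rate ``rho * T`` per site (total
branch length 2T times rho/2 per lineage), and at a breakpoint the
detached lineage re-coalesces either into its own branch (TMRCA unchanged)
or into the partner lineage (new TMRCA).  SMC' preserves the Exp(1)
marginal exactly, unlike plain SMC.

Given the local TMRCA ``T``, each site mismatches with probability
``pi * T`` (clamped at 0.95; clamping events are counted and warned about
when they exceed 0.1% of sites).  ``pi`` and ``rho`` are both per-site,
population-scaled rates on the same scale, so ``E[mismatch fraction] = pi``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .index import SequencePool, decode, load_pool

__all__ = ["SimPair", "simulate_pair", "export_unaligned", "random_pool"]

_CLAMP = 0.95


def _base_probs(gc_content: float) -> np.ndarray:
    half_gc = gc_content / 2.0
    half_at = (1.0 - gc_content) / 2.0
    return np.array([half_at, half_gc, half_gc, half_at])  # A C G T


def _smc_prime_transition(T: float, rng: np.random.Generator) -> float:
    """New TMRCA after a recombination breakpoint, SMC' style.

    The breakpoint height ``u`` is uniform on (0, T) (uniform on the two
    branches of total length 2T, which are exchangeable).  The floating
    lineage re-coalesces at rate 2 while both old branches exist (below T)
    and rate 1 above; a re-coalescence below T lands on the old own branch
    with probability 1/2, leaving the TMRCA unchanged.
    """
    u = rng.uniform(0.0, T)
    e = rng.exponential()
    if e < 2.0 * (T - u):
        if rng.random() < 0.5:
            return T  # back-coalescence into the same branch: invisible
        return u + e / 2.0
    return T + (e - 2.0 * (T - u))


def _tmrca_segments(L: int, rho: float, rng: np.random.Generator):
    """Segment starts and TMRCAs of the SMC' process over L sites."""
    starts: list[int] = []
    times: list[float] = []
    pos = 0
    T = rng.exponential()
    while pos < L:
        starts.append(pos)
        times.append(T)
        if rho <= 0.0:
            pos = L
            break
        p_break = -np.expm1(-rho * T)  # per-site breakpoint probability
        pos += int(rng.geometric(p_break))
        if pos < L:
            T = _smc_prime_transition(T, rng)
    return np.array(starts, dtype=np.int64), np.array(times)


@dataclass
class SimPair:
    """A simulated pair of homologous sequences with full truth.

    ``seq_a``/``seq_b`` are uint8 base codes; ``tmrca`` is the per-site
    coalescence time (coalescent units, mean 1); ``mismatch_mask`` marks
    sites where the two sequences differ.
    """

    seq_a: np.ndarray
    seq_b: np.ndarray
    tmrca: np.ndarray
    mismatch_mask: np.ndarray
    params: dict = field(default_factory=dict)
    n_clamped: int = 0

    @property
    def L(self) -> int:
        return len(self.seq_a)

    @property
    def seq_a_str(self) -> str:
        return decode(self.seq_a)

    @property
    def seq_b_str(self) -> str:
        return decode(self.seq_b)

    @property
    def mismatch_fraction(self) -> float:
        return float(np.mean(self.mismatch_mask))


def simulate_pair(
    L: int,
    pi: float,
    rho: float,
    gc_content: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SimPair:
    """Simulate one query/subject pair of length ``L``.

    Draws the per-site TMRCA under SMC', then mismatches with per-site
    probability ``min(pi * T, 0.95)``, then nucleotides with the requested
    GC-content; mismatched sites of the second sequence are re-drawn from
    the base distribution conditioned on differing.  Fully reproducible
    from ``seed``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0.0 < pi < 1.0:
        raise ValueError("pi must lie in (0, 1)")
    if rho < 0.0:
        raise ValueError("rho must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)

    starts, times = _tmrca_segments(L, rho, rng)
    seg_lens = np.diff(np.append(starts, L))
    tmrca = np.repeat(times, seg_lens)

    p_mis = pi * tmrca
    n_clamped = int(np.count_nonzero(p_mis > _CLAMP))
    if n_clamped > 0.001 * L:
        warnings.warn(
            f"mismatch probability pi*T clamped at {_CLAMP} for {n_clamped} of {L} "
            "sites; pi is too large for the linear mutation approximation",
            RuntimeWarning,
            stacklevel=2,
        )
    np.clip(p_mis, None, _CLAMP, out=p_mis)
    mismatch_mask = rng.random(L) < p_mis

    probs = _base_probs(gc_content)
    cum = np.cumsum(probs)
    seq_a = np.searchsorted(cum, rng.random(L), side="right").astype(np.uint8)
    seq_b = seq_a.copy()

    idx = np.nonzero(mismatch_mask)[0]
    if len(idx) > 0:
        # per-base conditional distribution over the three other bases
        cond = np.tile(probs, (4, 1))
        np.fill_diagonal(cond, 0.0)
        cond /= cond.sum(axis=1, keepdims=True)
        cond_cum = np.cumsum(cond, axis=1)
        u = rng.random(len(idx))
        rows = cond_cum[seq_a[idx]]
        seq_b[idx] = (u[:, None] < rows).argmax(axis=1).astype(np.uint8)

    return SimPair(
        seq_a=seq_a,
        seq_b=seq_b,
        tmrca=tmrca,
        mismatch_mask=mismatch_mask,
        params={"pi": pi, "rho": rho, "L": L, "gc_content": gc_content, "seed": seed},
        n_clamped=n_clamped,
    )


def _fragment(codes: np.ndarray, n_contigs: int, prefix: str, rng: np.random.Generator):
    L = len(codes)
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    if n_contigs > L:
        raise ValueError("cannot split a sequence into more contigs than sites")
    cuts = np.sort(rng.choice(np.arange(1, L), size=n_contigs - 1, replace=False))
    edges = np.concatenate([[0], cuts, [L]])
    order = rng.permutation(n_contigs)
    records = []
    for j in order:
        a, b = int(edges[j]), int(edges[j + 1])
        records.append((f"{prefix}_{a}_{b}", decode(codes[a:b])))
    return records


def export_unaligned(
    sim_pair: SimPair,
    n_contigs_a: int = 1,
    n_contigs_b: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
):
    """Export the pair as two unaligned, contig-fragmented record sets.

    Each sequence is split at uniform random points into the requested
    number of contigs and the contig order is shuffled; record ids encode
    the original half-open offsets, so the alignment can be recovered in
    tests but is absent from the sequence data itself.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    recs_a = _fragment(sim_pair.seq_a, n_contigs_a, "a", rng)
    recs_b = _fragment(sim_pair.seq_b, n_contigs_b, "b", rng)
    return recs_a, recs_b


def random_pool(
    L: int,
    gc_content: float = 0.5,
    seed: int | None = None,
    strand_double: bool = True,
) -> SequencePool:
    """I.i.d. random sequence pool with the given GC-content."""
    if L < 1:
        raise ValueError("L must be >= 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(_base_probs(gc_content))
    codes = np.searchsorted(cum, rng.random(L), side="right").astype(np.uint8)
    return load_pool([("random", decode(codes))], strand_double=strand_double)
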