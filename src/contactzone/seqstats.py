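"""Mitochondrial sequence statistics: Tajima's D, Fu's Fs, variable and
parsimony-informative sites, codon-position and synonymous/non-synonymous
tallies, uncorrected p-distances, and the common/rare haplotype partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .datatypes import HaplotypeAlignment

VALID = frozenset(b"ACGT")
VALID_BYTES = [b"A", b"C", b"G", b"T"]
COMMON_THRESHOLD = 9  # haplotypes carried by > 9 individuals are "common"


# ---------------------------------------------------------------------------
# Neutrality statistics
# ---------------------------------------------------------------------------


@dataclass
class NeutralityStats:
    n: int
    s: int
    pi: float
    theta_w: float
    tajimas_d: float   # NaN when S == 0
    fus_fs: float      # NaN when S == 0
    defined: bool


def _char_matrix(aln: HaplotypeAlignment, mode: str) -> np.ndarray:
    if mode not in ("haplotypes", "individuals"):
        raise ValueError("mode must be 'haplotypes' or 'individuals'")
    return aln.matrix(expand=(mode == "individuals"))


def _segregating_sites(mat: np.ndarray) -> np.ndarray:
    """Indices of columns with >= 2 distinct unambiguous states."""
    out = []
    for j in range(mat.shape[1]):
        col = mat[:, j]
        states = {c for c in col.tolist() if c[0] in VALID}
        if len(states) >= 2:
            out.append(j)
    return np.array(out, dtype=int)


def _pairwise_diffs(mat: np.ndarray) -> np.ndarray:
    """(n, n) matrix of pairwise mismatch counts (pairwise deletion)."""
    n = mat.shape[0]
    valid = np.isin(mat, VALID_BYTES)
    d = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        d[i, i + 1:] = ((mat[i] != mat[i + 1:]) & both).sum(axis=1)
    return d + d.T


def _log_stirling_row(n: int) -> np.ndarray:
    """log |S(n, k)| (unsigned first-kind Stirling), k = 0..n, via the
    recursion |S(n+1,k)| = n|S(n,k)| + |S(n,k-1)| on the log scale."""
    row = np.full(n + 1, -np.inf)
    row[0] = -np.inf if n else 0.0
    cur = np.array([-np.inf, 0.0]) if n >= 1 else np.array([0.0])  # S(1, .)
    if n == 0:
        return np.array([0.0])
    for m in range(1, n):
        nxt = np.full(m + 2, -np.inf)
        for k in range(1, m + 2):
            terms = []
            if k <= m:
                terms.append(np.log(m) + cur[k])
            if k - 1 <= m:
                terms.append(cur[k - 1])
            nxt[k] = np.logaddexp.reduce(terms) if terms else -np.inf
        cur = nxt
    return cur


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """Pr(K = k | theta, n) under the Ewens sampling formula, k = 0..n."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    logs = _log_stirling_row(n)
    k = np.arange(n + 1)
    logp = logs + k * np.log(theta)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    logp = logp - log_rising
    with np.errstate(under="ignore"):
        p = np.exp(logp)
    p[~np.isfinite(p)] = 0.0
    return p


def fus_fs(n: int, k_obs: int, theta_pi: float) -> float:
    """Fu's Fs = ln(S' / (1 - S')) with S' = Pr(K >= k_obs | theta_pi)."""
    if theta_pi <= 0:
        return np.nan
    p = ewens_k_distribution(n, theta_pi)
    s_prime = p[k_obs:].sum()
    s_prime = min(max(s_prime, 1e-300), 1 - 1e-15)
    return float(np.log(s_prime / (1 - s_prime)))


def neutrality_stats(aln: HaplotypeAlignment,
                     mode: str = "individuals") -> NeutralityStats:
    """Tajima's D and Fu's Fs over the alignment.

    ``mode='individuals'`` expands haplotypes by their carrier counts (the
    sample of sequences); ``mode='haplotypes'`` uses each haplotype once.
    Both are provided because published values do not always state which
    sample was used. D and Fs are flagged undefined when S = 0.
    """
    mat = _char_matrix(aln, mode)
    n = mat.shape[0]
    if n < 4:
        raise ValueError("need >= 4 sequences for Tajima's D")
    seg = _segregating_sites(mat)
    S = len(seg)
    d = _pairwise_diffs(mat)
    iu = np.triu_indices(n, k=1)
    pi = float(d[iu].mean())
    a1 = np.sum(1.0 / np.arange(1, n))
    theta_w = S / a1
    if S == 0:
        return NeutralityStats(n, 0, 0.0, 0.0, np.nan, np.nan, defined=False)
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    D = (pi - theta_w) / np.sqrt(var)
    # number of distinct alleles (haplotypes) in the analysed sample
    k_obs = len({mat[i].tobytes() for i in range(n)})
    fs = fus_fs(n, k_obs, pi)
    return NeutralityStats(n, S, pi, theta_w, float(D), fs, defined=True)


# ---------------------------------------------------------------------------
# Alignment site statistics
# ---------------------------------------------------------------------------


@dataclass
class SeqSiteStats:
    n_variable: int
    n_parsimony_informative: int
    variable_by_codon_position: tuple[int, int, int]
    n_synonymous: int
    n_nonsynonymous: int
    p_distance: np.ndarray          # proportions, pairwise deletion
    common: list[str]
    rare: list[str]
    frame: int
    variable_positions: list[int] = field(default_factory=list)


def _consensus(mat: np.ndarray) -> np.ndarray:
    cons = []
    for j in range(mat.shape[1]):
        col = [c for c in mat[:, j].tolist() if c[0] in VALID]
        if not col:
            cons.append(b"N")
            continue
        vals, cnt = np.unique(col, return_counts=True)
        top = cnt.max()
        cons.append(sorted(v for v, c in zip(vals, cnt) if c == top)[0])
    return np.array(cons)


def _stop_positions(seq: str, frame: int, table) -> list[int]:
    sub = seq[frame:]
    sub = sub[: len(sub) - len(sub) % 3]
    stops = []
    for i in range(0, len(sub), 3):
        codon = sub[i:i + 3]
        if codon in table.stop_codons:
            stops.append(frame + i)
    return stops


def choose_frame(aln: HaplotypeAlignment, table_id: int = 5) -> int:
    """Smallest reading frame whose translation of every sequence is free of
    internal stops; raises with per-frame stop positions when none exists."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    report = {}
    for frame in (0, 1, 2):
        stops = {i: _stop_positions(s, frame, table)
                 for i, s in zip(aln.ids, aln.seqs)}
        if not any(stops.values()):
            return frame
        report[frame] = {i: p for i, p in stops.items() if p}
    raise ValueError(f"no stop-free reading frame; stop positions: {report}")


def sequence_site_stats(aln: HaplotypeAlignment, table_id: int = 5,
                        frame: int | None = None) -> SeqSiteStats:
    """Site statistics on an aligned coding fragment.

    Variable sites have >= 2 observed unambiguous states; parsimony-
    informative sites have >= 2 states each carried by >= 2 sequences.
    Codon positions are relative to ``frame`` (auto-chosen as the first
    stop-free frame under the invertebrate mitochondrial code when None).
    Synonymous/non-synonymous classification compares each observed variant
    state to the majority-rule consensus codon. p-distances use pairwise
    deletion of ambiguous positions. Haplotypes carried by more than
    9 individuals are "common".
    """
    if frame is None:
        frame = choose_frame(aln, table_id)
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mat = aln.matrix(expand=False)
    n, L = mat.shape
    seg = _segregating_sites(mat)
    pos_counts = [0, 0, 0]
    informative = 0
    for j in seg:
        pos_counts[(j - frame) % 3] += 1
        col = [c for c in mat[:, j].tolist() if c[0] in VALID]
        vals, cnt = np.unique(col, return_counts=True)
        if (cnt >= 2).sum() >= 2:
            informative += 1

    cons = _consensus(mat)
    syn = nonsyn = 0
    for j in seg:
        cp = (j - frame) % 3
        start = j - cp
        if start < frame or start + 3 > L:
            continue
        cons_codon = b"".join(cons[start:start + 3]).decode()
        if any(b not in "ACGT" for b in cons_codon):
            continue
        ref_aa = str(Seq(cons_codon).translate(table=table_id))
        col = {c for c in mat[:, j].tolist() if c[0] in VALID}
        for state in sorted(col):
            if state == cons[j]:
                continue
            var_codon = list(cons_codon)
            var_codon[cp] = state.decode()
            var_codon = "".join(var_codon)
            if var_codon in table.stop_codons:
                nonsyn += 1
                continue
            aa = str(Seq(var_codon).translate(table=table_id))
            if aa == ref_aa:
                syn += 1
            else:
                nonsyn += 1

    diffs = _pairwise_diffs(mat)
    valid = np.isin(mat, VALID_BYTES)
    comp = valid.astype(int) @ valid.astype(int).T
    with np.errstate(divide="ignore", invalid="ignore"):
        pdist = np.where(comp > 0, diffs / comp, np.nan)
    np.fill_diagonal(pdist, 0.0)

    common = [i for i, cnt in zip(aln.ids, aln.counts) if cnt > COMMON_THRESHOLD]
    rare = [i for i in aln.ids if i not in common]
    return SeqSiteStats(
        n_variable=len(seg),
        n_parsimony_informative=informative,
        variable_by_codon_position=tuple(pos_counts),
        n_synonymous=syn,
        n_nonsynonymous=nonsyn,
        p_distance=pdist,
        common=common,
        rare=rare,
        frame=frame,
        variable_positions=[int(j) for j in seg],
    )
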