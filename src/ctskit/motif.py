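"""Position-weight-matrix machinery.

Log-odds scoring in bits against a 0-order background, exact p-values via
dynamic-programming convolution of the discretized per-column score
distribution, both-strand threshold scanning, and a one-occurrence-per-
sequence (OOPS) EM motif discoverer.

The p-value of a score s is P(Score >= s) for a random word drawn from the
background model. Scores are discretized on a fixed grid (default 1/1000
bit); the scanner computes each window's discretized score with the same
per-column integer bins that the distribution convolves, so the p-value
attached to a hit is exact with respect to the discretized matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .genomic_io import reverse_complement

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_GRANULARITY = 1e-3  # bits per bin
DEFAULT_P_THRESHOLD = 1e-4


def encode(seq: str) -> np.ndarray:
    """Encode A,C,G,T as 0..3 and anything else as 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


class DegenerateInputError(ValueError):
    pass


@dataclass(frozen=True)
class PWM:
    """Base-probability matrix of a motif plus its background model.

    probs has shape (4, w) with columns summing to 1; background is a
    length-4 probability vector (A, C, G, T order).
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)
        if probs.ndim != 2 or probs.shape[0] != 4:
            raise ValueError("probs must be a 4 x w matrix")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if self.pseudocount > 0 and np.any(probs <= 0):
            raise ValueError("positive pseudocount implies positive probs")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        """(4, w) matrix of log2(p/bg); -inf where p == 0."""
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background[:, None])

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=0))

    @property
    def information_content(self) -> float:
        """Total IC in bits relative to the background."""
        lo = self.log_odds
        finite = np.where(np.isfinite(lo), lo, 0.0)
        return float(np.sum(self.probs * finite))

    def reverse_complement(self) -> "PWM":
        return PWM(self.probs[::-1, ::-1].copy(), self.background[::-1].copy(),
                   self.pseudocount)


def build_pwm(
    counts,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background=None,
) -> PWM:
    """PWM from a 4 x w count matrix.

    The pseudocount is distributed by background frequency:
    p[b][j] = (counts[b][j] + pc * bg[b]) / (colsum_j + pc).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("counts must be a 4 x w matrix")
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    bg = (
        np.full(4, 0.25)
        if background is None
        else np.asarray(background, dtype=float)
    )
    colsums = counts.sum(axis=0)
    if pseudocount <= 0 and np.any(colsums == 0):
        raise DegenerateInputError(
            "zero column sum with zero pseudocount"
        )
    probs = (counts + pseudocount * bg[:, None]) / (colsums + pseudocount)
    return PWM(probs, bg, pseudocount)


def logodds_score(pwm: PWM, word: str, strand: str = "+") -> float:
    """Log-odds score of a w-mer in bits; minus strand scores the
    reverse complement of the word. Returns nan for words containing N."""
    if strand == "-":
        word = reverse_complement(word)
    codes = encode(word)
    if len(codes) != pwm.width:
        raise ValueError(f"word length {len(codes)} != motif width {pwm.width}")
    if np.any(codes == 4):
        return float("nan")
    return float(pwm.log_odds[codes, np.arange(pwm.width)].sum())


@dataclass
class ScoreDistribution:
    """Exact pmf of the discretized log-odds score under the background.

    Bin k holds P(sum of per-column bins == k + offset); a word's bin is
    the sum of round(log_odds / granularity) over its columns.
    """

    granularity: float
    offset: int  # bin index of pmf[0]
    pmf: np.ndarray
    _sf: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        self._sf = np.cumsum(self.pmf[::-1])[::-1]

    @property
    def min_score(self) -> float:
        return self.offset * self.granularity

    @property
    def max_score(self) -> float:
        return (self.offset + len(self.pmf) - 1) * self.granularity

    def sf_at_bin(self, k: int) -> float:
        """P(binned score >= k)."""
        i = k - self.offset
        if i <= 0:
            return 1.0
        if i >= len(self.pmf):
            return 0.0
        return float(self._sf[i])

    def pvalue(self, score_bits: float) -> float:
        return self.sf_at_bin(int(round(score_bits / self.granularity)))


def _column_bins(pwm: PWM, granularity: float) -> np.ndarray:
    """(4, w) integer score bins; -inf log-odds maps to a very low bin."""
    lo = pwm.log_odds
    finite_min = np.min(lo[np.isfinite(lo)]) if np.any(np.isfinite(lo)) else 0.0
    floor = min(finite_min, 0.0) - 100.0  # sentinel well below any real score
    lo = np.where(np.isfinite(lo), lo, floor)
    return np.round(lo / granularity).astype(np.int64)


def score_distribution(
    pwm: PWM, granularity: float = DEFAULT_GRANULARITY
) -> ScoreDistribution:
    """Exact score pmf by iterated convolution over columns.

    Each column contributes one of four binned scores with its background
    probability; the pmf of the sum is built column by column.
    """
    if granularity <= 0:
        raise ValueError("granularity must be positive")
    bins = _column_bins(pwm, granularity)
    bg = pwm.background
    lo_bound = int(bins.min(axis=0).sum())
    hi_bound = int(bins.max(axis=0).sum())
    size = hi_bound - lo_bound + 1
    pmf = np.zeros(size)
    # running support: [cur_lo, cur_lo + cur_len)
    pmf[0] = 1.0
    cur_lo = 0
    cur_len = 1
    for j in range(pwm.width):
        col = bins[:, j]
        new_lo = cur_lo + int(col.min())
        new_len = cur_len + int(col.max() - col.min())
        new = np.zeros(new_len)
        for b in range(4):
            if bg[b] == 0:
                continue
            shift = int(col[b]) + cur_lo - new_lo
            new[shift : shift + cur_len] += bg[b] * pmf[:cur_len]
        pmf = new
        cur_lo, cur_len = new_lo, new_len
    assert cur_lo == lo_bound and cur_len == size
    return ScoreDistribution(granularity, lo_bound, pmf)


def score_to_pvalue(dist: ScoreDistribution, score_bits: float) -> float:
    """P(Score >= s) under the background; 1.0 at or below the support min."""
    return dist.pvalue(score_bits)


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded motif occurrence; span is [start, start+width)."""

    chrom: str
    start: int
    strand: str
    score: float  # log-odds, bits
    pvalue: float
    width: int

    @property
    def end(self) -> int:
        return self.start + self.width


def _window_bin_scores(codes: np.ndarray, mat: np.ndarray, w: int):
    """Sliding-window sums of mat[code, column]; windows with N get None mask.

    Returns (scores, valid) arrays of length len(codes) - w + 1.
    """
    n = len(codes) - w + 1
    if n <= 0:
        return np.empty(0, mat.dtype), np.empty(0, bool)
    windows = np.lib.stride_tricks.sliding_window_view(codes, w)
    valid = ~(windows == 4).any(axis=1)
    safe = np.where(windows == 4, 0, windows)
    scores = mat[safe, np.arange(w)].sum(axis=1)
    return scores, valid


def scan(
    sequence: str,
    pwm: PWM,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    chrom: str = ".",
    offset: int = 0,
    granularity: float = DEFAULT_GRANULARITY,
    dist: ScoreDistribution | None = None,
) -> list[MotifHit]:
    """Report every position/strand with motif p-value < p_threshold.

    Both strands are scanned; coordinates are forward-strand starts
    (plus ``offset``). Windows containing N are skipped. Palindromic
    double-reports at the same start are both kept.
    """
    if not (0 < p_threshold < 1):
        raise ValueError("p_threshold must be in (0, 1)")
    w = pwm.width
    codes = encode(sequence)
    if len(codes) < w:
        return []
    if dist is None:
        dist = score_distribution(pwm, granularity)
    bins = _column_bins(pwm, granularity)
    lo_float = pwm.log_odds
    lo_float = np.where(np.isfinite(lo_float), lo_float, -1e4)
    # minimal bin whose survival probability is below threshold
    sf = dist._sf
    below = np.nonzero(sf < p_threshold)[0]
    if len(below) == 0:
        return []
    min_bin = int(below[0]) + dist.offset

    hits: list[MotifHit] = []
    for strand in "+-":
        if strand == "+":
            b_mat, f_mat = bins, lo_float
        else:
            b_mat = bins[::-1, ::-1]
            f_mat = lo_float[::-1, ::-1]
        bscores, valid = _window_bin_scores(codes, b_mat, w)
        fscores, _ = _window_bin_scores(codes, f_mat, w)
        idx = np.nonzero(valid & (bscores >= min_bin))[0]
        for i in idx:
            k = int(bscores[i])
            hits.append(
                MotifHit(
                    chrom=chrom,
                    start=offset + int(i),
                    strand=strand,
                    score=float(fscores[i]),
                    pvalue=dist.sf_at_bin(k),
                    width=w,
                )
            )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def write_hits(dest, hits: Sequence[MotifHit]) -> None:
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w")
        close = True
    try:
        dest.write("chrom\tstart\tend\tstrand\tscore_bits\tpvalue\n")
        for h in hits:
            dest.write(
                f"{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.score:.4f}\t{h.pvalue:.3e}\n"
            )
    finally:
        if close:
            dest.close()


# ---------------------------------------------------------------------------
# MEME minimal format


def write_meme(dest, pwm: PWM, name: str = "motif1") -> None:
    close = False
    if not hasattr(dest, "write"):
        dest = open(dest, "w")
        close = True
    try:
        bg = pwm.background
        dest.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        dest.write(
            "Background letter frequencies\n"
            f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
        )
        dest.write(f"MOTIF {name}\n")
        dest.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= 20 E= 0\n"
        )
        for j in range(pwm.width):
            dest.write(
                " ".join(f"{pwm.probs[b, j]:.6f}" for b in range(4)) + "\n"
            )
    finally:
        if close:
            dest.close()


def read_meme(source) -> PWM:
    """Read the first motif from a MEME-minimal motif file."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source) as fh:
            lines = fh.read().splitlines()
    bg = np.full(4, 0.25)
    rows: list[list[float]] = []
    w = None
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            freq = {parts[k]: float(parts[k + 1]) for k in range(0, len(parts), 2)}
            bg = np.array([freq.get(b, 0.25) for b in BASES])
            i += 2
            continue
        if line.startswith("letter-probability matrix"):
            tokens = line.replace("=", " = ").split()
            if "w" in tokens:
                w = int(tokens[tokens.index("w") + 2])
            i += 1
            while i < len(lines):
                parts = lines[i].split()
                if len(parts) != 4:
                    break
                try:
                    rows.append([float(x) for x in parts])
                except ValueError:
                    break
                i += 1
            break
        i += 1
    if not rows:
        raise ValueError("no letter-probability matrix found")
    probs = np.array(rows).T
    probs = probs / probs.sum(axis=0)
    if w is not None and probs.shape[1] != w:
        raise ValueError("matrix row count disagrees with declared width")
    return PWM(probs, bg)


# ---------------------------------------------------------------------------
# OOPS EM motif discovery


@dataclass
class DiscoveryResult:
    pwm: PWM
    log_likelihood: float
    trace: list[float]  # per-iteration observed-data log-likelihood
    restart: int


def _seqs_to_codes(sequences: Sequence[str], w: int) -> list[np.ndarray]:
    codes = []
    for s in sequences:
        if len(s) < w:
            raise ValueError(
                f"sequence of length {len(s)} shorter than motif width {w}"
            )
        codes.append(encode(s))
    if len(codes) < 2:
        raise ValueError("need at least 2 sequences")
    return codes


def _top_kmers(codes: list[np.ndarray], w: int, k: int, rng) -> list[np.ndarray]:
    counts: dict[bytes, int] = {}
    for c in codes:
        if len(c) < w:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(c, w)
        for win in windows[(windows != 4).all(axis=1)]:
            key = win.tobytes()
            counts[key] = counts.get(key, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    picks = [np.frombuffer(key, dtype=np.int8) for key, _ in items[:k]]
    while len(picks) < k:  # fewer distinct w-mers than restarts
        picks.append(rng.integers(0, 4, size=w).astype(np.int8))
    return picks


def _seed_pwm(kmer: np.ndarray, background: np.ndarray, match: float = 0.6) -> PWM:
    w = len(kmer)
    probs = np.tile(((1 - match) * background)[:, None], (1, w))
    probs[kmer, np.arange(w)] += match
    probs /= probs.sum(axis=0)
    return PWM(probs, background)


def discover_motif_oops(
    sequences: Sequence[str],
    w: int = 20,
    use_revcomp: bool = True,
    seed: int = 0,
    n_restarts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    background=None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DiscoveryResult:
    """One-occurrence-per-sequence EM motif discovery.

    Each sequence is assumed to contain exactly one motif instance at a
    uniformly distributed position (and strand, when ``use_revcomp``). The
    E-step computes the posterior over placements from the current PWM's
    log-odds; the M-step re-estimates the PWM from posterior-weighted base
    counts. Restarts are seeded from the most frequent w-mers; the best
    final observed-data log-likelihood wins.
    """
    codes = _seqs_to_codes(sequences, w)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    rng = np.random.default_rng(seed)
    seeds = _top_kmers(codes, w, n_restarts, rng)

    # Precompute per-sequence one-hot window tensors W[i, b, j] =
    # [window_i base at column j == b], plus the reverse-complement view, so
    # E- and M-steps reduce to einsums.
    fwd: list[np.ndarray] = []
    rev: list[np.ndarray] = []
    for c in codes:
        windows = np.lib.stride_tricks.sliding_window_view(c, w)
        valid = ~(windows == 4).any(axis=1)
        windows = windows[valid]
        if len(windows) == 0:
            raise ValueError("a sequence has no N-free window of motif width")
        onehot = np.zeros((len(windows), 4, w), dtype=np.float32)
        ii = np.arange(len(windows))[:, None]
        jj = np.arange(w)[None, :]
        safe = np.clip(windows, 0, 3)
        onehot[ii, safe, jj] = 1.0
        fwd.append(onehot)
        # reverse complement: column j reads base complement(win[w-1-j])
        rev.append(onehot[:, ::-1, ::-1].copy())

    ln2 = np.log(2.0)
    best: DiscoveryResult | None = None
    for restart, kmer in enumerate(seeds):
        pwm = _seed_pwm(kmer, bg)
        trace: list[float] = []
        prev = -np.inf
        for _ in range(max_iter):
            lo = np.where(np.isfinite(pwm.log_odds), pwm.log_odds, -1e4)
            lo32 = lo.astype(np.float32)
            ll_total = 0.0
            counts = np.zeros((4, w))
            for W, R in zip(fwd, rev):
                sf = np.einsum("ibj,bj->i", W, lo32)
                parts = [sf]
                if use_revcomp:
                    parts.append(np.einsum("ibj,bj->i", R, lo32))
                logw = np.concatenate(parts).astype(float) * ln2
                lz = logsumexp(logw)
                # per-sequence contribution to the observed-data
                # log-likelihood ratio vs pure background
                ll_total += float(lz - np.log(len(logw)))
                post = np.exp(logw - lz)
                npos = len(sf)
                counts += np.einsum("i,ibj->bj", post[:npos], W)
                if use_revcomp:
                    counts += np.einsum("i,ibj->bj", post[npos:], R)
            trace.append(float(ll_total))
            pwm = build_pwm(counts, pseudocount=pseudocount, background=bg)
            if np.isfinite(prev) and abs(ll_total - prev) <= tol * max(
                1.0, abs(prev)
            ):
                break
            prev = ll_total
        result = DiscoveryResult(pwm, trace[-1], trace, restart)
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    assert best is not None
    return best
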