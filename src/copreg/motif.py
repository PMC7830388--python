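"""Motif discovery and scanning for the regulon's binding site.

Discovery is expectation-maximization under a ZOOPS model (zero or one
motif occurrence per sequence, either strand) with a 0-order background
estimated from intergenic sequence; widths 8-18 are compared by a
BIC-penalized likelihood. Scanning computes log-odds scores with exact
p-values from a dynamic program over integer-discretized scores and
controls the FDR over all scanned positions with Benjamini-Hochberg
q-values (default q < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from ._utils import encode, revcomp, sub_rng
from .dge import bh_adjust

__all__ = [
    "MotifModel",
    "estimate_background",
    "zoops_em",
    "choose_width",
    "consensus_iupac",
    "scan_pwm",
    "palindromicity",
    "information_content",
]

_PAIR_CODES = {
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}


@dataclass
class MotifModel:
    """Column-stochastic probability matrix with ZOOPS occurrence prior."""

    width: int
    theta: np.ndarray  # (4, width), columns sum to 1
    background: np.ndarray  # (4,)
    gamma: float  # per-sequence occurrence prior
    log_likelihood: float = np.nan
    ll_history: list[float] = field(default_factory=list)
    # penalized EM objective (data LL + Dirichlet smoothing term); this is
    # the quantity guaranteed non-decreasing across iterations
    objective_history: list[float] = field(default_factory=list)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.theta.shape != (4, self.width):
            raise ValueError("theta must be 4 x width")
        if not np.allclose(self.theta.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("theta columns must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0, 1]")

    @property
    def consensus(self) -> str:
        return consensus_iupac(self.theta)


def estimate_background(intergenic_sequences: list[str]) -> np.ndarray:
    """0-order background from intergenic sequence, both strands pooled.

    +1 pseudocount per base; pooling the two strands makes the composition
    strand-symmetric (f_A = f_T, f_C = f_G).
    """
    counts = np.zeros(4, dtype=float)
    for seq in intergenic_sequences:
        idx = encode(seq)
        counts += np.bincount(idx[idx < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("no A/C/G/T bases in the background input")
    counts += 1.0
    total = counts.sum()
    sym = np.empty(4)
    sym[0] = sym[3] = (counts[0] + counts[3]) / (2 * total)  # A, T
    sym[1] = sym[2] = (counts[1] + counts[2]) / (2 * total)  # C, G
    return sym


class _WindowData:
    """Flat precomputation of every offset x strand window across a set.

    Windows are stored as one (n_windows, w) index matrix (4 = N) with each
    sequence's forward-then-reverse-complement windows contiguous, so the
    per-sequence E-step reductions become `reduceat` segment operations.
    """

    def __init__(self, sequences: list[str], w: int, background: np.ndarray):
        blocks, m_per_seq = [], []
        logbg = np.log(background)
        self.logbg_const = 0.0
        for seq in sequences:
            if len(seq) < w:
                raise ValueError(f"sequence of length {len(seq)} shorter than width {w}")
            idx = encode(seq)
            idx_rc = encode(revcomp(seq))
            blocks.append(sliding_window_view(idx, w))
            blocks.append(sliding_window_view(idx_rc, w))
            m_per_seq.append(len(seq) - w + 1)
            valid = idx < 4
            self.logbg_const += float(logbg[idx[valid]].sum())
        self.windows = np.ascontiguousarray(np.concatenate(blocks)).astype(np.int64)
        self.m = np.asarray(m_per_seq)
        sizes = 2 * self.m
        self.starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        self.n_seq = len(sequences)
        # flattened (window, column) index pairs for the M-step scatter-add
        w_cols = np.tile(np.arange(w), len(self.windows))
        self.flat_idx = (self.windows.ravel() * w + w_cols, )
        self.cols = np.arange(w)


def _em_once(
    data: _WindowData,
    w: int,
    background: np.ndarray,
    theta0: np.ndarray,
    gamma0: float,
    max_iter: int,
    tol: float,
    pseudocount: float = 0.01,
) -> MotifModel:
    theta, gamma = theta0.copy(), gamma0
    logbg = np.log(background)
    ll_history: list[float] = []
    obj_history: list[float] = []
    log_site_prior = -np.log(2 * data.m)  # uniform over offsets x strands
    for _ in range(max_iter):
        log_theta = np.log(theta)
        log_ratio5 = np.vstack([log_theta - logbg[:, None], np.zeros(w)])  # N scores 0
        scores = log_ratio5[data.windows, data.cols].sum(axis=1)
        b = np.log(gamma) + np.repeat(log_site_prior, 2 * data.m) + scores
        b0 = np.log1p(-gamma)
        seg_max = np.maximum.reduceat(b, data.starts)
        M = np.maximum(seg_max, b0)
        a = np.exp(b - np.repeat(M, 2 * data.m))
        seg_sum = np.add.reduceat(a, data.starts)
        z = np.exp(b0 - M) + seg_sum
        ll = float((M + np.log(z)).sum()) + data.logbg_const
        ll_history.append(ll)
        # the EM objective includes the Dirichlet smoothing term and is the
        # quantity the E/M updates provably never decrease
        obj_history.append(ll + pseudocount * log_theta.sum())
        # M-step
        post = a / np.repeat(z, 2 * data.m)
        counts5 = np.zeros(5 * w)
        np.add.at(counts5, data.flat_idx[0], np.repeat(post, w))
        counts = counts5.reshape(5, w)[:4] + pseudocount
        theta = counts / counts.sum(axis=0, keepdims=True)
        gamma_post = 1.0 - np.exp(b0 - M) / z
        gamma = float(np.clip(gamma_post.mean(), 1e-6, 1 - 1e-6))
        if len(obj_history) > 1:
            gain = obj_history[-1] - obj_history[-2]
            if gain < -1e-6:
                raise RuntimeError(f"EM objective decreased by {-gain:.3g}")
            if gain < tol:
                break
    return MotifModel(width=w, theta=theta, background=background, gamma=gamma,
                      log_likelihood=ll_history[-1], ll_history=ll_history,
                      objective_history=obj_history)


def _seed_theta(word: str, w: int) -> np.ndarray:
    theta0 = np.full((4, w), 0.1)
    for k, b in enumerate(encode(word)):
        if b < 4:
            theta0[b, k] = 0.7
    return theta0 / theta0.sum(axis=0, keepdims=True)


def zoops_em(
    sequences: list[str],
    w: int,
    background: np.ndarray,
    n_starts: int = 24,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
    n_refine: int = 3,
) -> MotifModel:
    """ZOOPS EM motif discovery at a fixed width; best of seeded restarts.

    Each restart initializes theta from a randomly chosen w-mer (0.7 on its
    base, 0.1 elsewhere; random strand) and gamma at 0.5. Restarts are
    staged: every start runs a few burn-in iterations, then the
    ``n_refine`` best by EM objective run to convergence -- cheap
    protection against register-shifted local optima. Per-iteration traces
    are kept on the returned model: ``ll_history`` (data log-likelihood)
    and ``objective_history`` (the penalized EM objective, which the
    updates provably never decrease; the data LL can dip by the tiny
    Dirichlet smoothing term).
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    background = np.asarray(background, dtype=float)
    data = _WindowData(sequences, w, background)
    rng = sub_rng(seed, "zoops", w)
    burnin: list[MotifModel] = []
    for _ in range(n_starts):
        si = rng.integers(len(sequences))
        seq = sequences[si]
        j = rng.integers(len(seq) - w + 1)
        word = seq[j:j + w]
        if rng.random() < 0.5:
            word = revcomp(word)
        burnin.append(_em_once(data, w, background, _seed_theta(word, w), 0.5,
                               max_iter=4, tol=0.0))
    burnin.sort(key=lambda m: m.objective_history[-1], reverse=True)
    best: MotifModel | None = None
    for cand in burnin[:max(1, n_refine)]:
        model = _em_once(data, w, background, cand.theta, cand.gamma, max_iter, tol)
        if best is None or model.log_likelihood > best.log_likelihood:
            best = model
    # column-shift refinement: re-seed EM from the converged matrix shifted
    # by a few columns (vacated columns filled with background) to escape
    # register-shifted local optima
    improved = True
    while improved:
        improved = False
        for shift in (-2, -1, 1, 2):
            theta_s = np.tile(background[:, None], (1, w))
            if shift > 0:
                theta_s[:, shift:] = best.theta[:, :w - shift]
            else:
                theta_s[:, :w + shift] = best.theta[:, -shift:]
            model = _em_once(data, w, background, theta_s, best.gamma, max_iter, tol)
            if model.log_likelihood > best.log_likelihood + 1e-9:
                best, improved = model, True
    return best


def choose_width(
    sequences: list[str],
    background: np.ndarray,
    widths=range(8, 19),
    n_starts: int = 5,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int = 0,
) -> MotifModel:
    """Run zoops_em per width and select by BIC-penalized log-likelihood.

    score(w) = LL - 0.5 * (3w + 1) * ln(total scanned positions); ties break
    towards the smaller width.
    """
    best, best_score = None, None
    for w in widths:
        child = int(np.random.SeedSequence([int(seed), int(w)]).generate_state(1)[0] % 2**31)
        model = zoops_em(sequences, w, background, n_starts, max_iter, tol, seed=child)
        n_scanned = sum(2 * (len(s) - w + 1) for s in sequences)
        score = model.log_likelihood - 0.5 * (3 * w + 1) * np.log(n_scanned)
        if best_score is None or score > best_score:
            best, best_score = model, score
    return best


def consensus_iupac(theta: np.ndarray, major: float = 0.6, pair: float = 0.8) -> str:
    """IUPAC consensus: dominant base, two-base code, or N per column."""
    theta = np.asarray(theta, dtype=float)
    out = []
    for col in theta.T:
        order = np.argsort(col)[::-1]
        if col[order[0]] >= major:
            out.append("ACGT"[order[0]])
        elif col[order[0]] + col[order[1]] >= pair:
            out.append(_PAIR_CODES[frozenset("ACGT"[i] for i in order[:2])])
        else:
            out.append("N")
    return "".join(out)


def _score_table_bits(model: MotifModel, granularity: float) -> np.ndarray:
    """(5, w) integer score table in units of `granularity` bits; row 4 = N = 0."""
    theta = np.maximum(model.theta, 1e-12)
    bits = np.log2(theta / model.background[:, None])
    table = np.zeros((5, model.width), dtype=np.int64)
    table[:4] = np.round(bits / granularity).astype(np.int64)
    return table


def score_distribution(model: MotifModel, granularity: float = 1e-3):
    """Exact null distribution of the integer-discretized log-odds score.

    Returns (int_table, offset, tail) where tail[s - offset] =
    P(score_int >= s) for a random word drawn column-wise from the
    background.
    """
    table = _score_table_bits(model, granularity)
    # iterative convolution over columns
    cur_lo, cur = 0, np.array([1.0])
    for k in range(model.width):
        col = table[:4, k]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            sh = cur_lo + int(col[b]) - new_lo
            new[sh:sh + len(cur)] += model.background[b] * cur
        cur, cur_lo = new, new_lo
    tail = np.cumsum(cur[::-1])[::-1]
    return table, cur_lo, tail


def _tail_prob(score_int: np.ndarray, offset: int, tail: np.ndarray) -> np.ndarray:
    idx = np.clip(score_int - offset, 0, len(tail) - 1)
    p = tail[idx]
    return np.where(score_int < offset, 1.0, p)


def scan_pwm(
    model: MotifModel,
    sequences: dict[str, str] | list[str],
    q_threshold: float = 0.05,
    granularity: float = 1e-3,
) -> pd.DataFrame:
    """Scan sequences on both strands with exact p-values and BH q-values.

    Every offset x strand in every sequence is scored; p-values come from
    the exact DP score distribution under the background (N bases contribute
    zero log-odds); q-values are BH over all scanned positions. Hits with
    q < ``q_threshold`` are returned sorted by (p, sequence id, offset).
    """
    if isinstance(sequences, list):
        sequences = {f"seq{i + 1}": s for i, s in enumerate(sequences)}
    table, offset, tail = score_distribution(model, granularity)
    w = model.width
    recs = []
    for sid in sorted(sequences):
        seq = sequences[sid]
        if len(seq) < w:
            continue
        idx = encode(seq)
        m = len(seq) - w + 1
        win = sliding_window_view(idx, w)
        cols = np.arange(w)
        s_fwd = table[win, cols].sum(axis=1)
        idx_rc = encode(revcomp(seq))
        win_rc = sliding_window_view(idx_rc, w)
        s_rc = table[win_rc, cols].sum(axis=1)
        for strand, scores in (("+", s_fwd), ("-", s_rc)):
            pvals = _tail_prob(scores, offset, tail)
            for j in range(m):
                off = j if strand == "+" else m - 1 - j
                word = seq[off:off + w]
                recs.append((sid, off, strand, scores[j] * granularity,
                             float(pvals[j]), word if strand == "+" else revcomp(word)))
    if not recs:
        return pd.DataFrame(
            columns=["sequence_id", "offset", "strand", "score", "pvalue", "qvalue", "matched"]
        )
    df = pd.DataFrame(
        recs, columns=["sequence_id", "offset", "strand", "score", "pvalue", "matched"]
    )
    df["qvalue"] = bh_adjust(df["pvalue"].to_numpy())
    hits = df[df["qvalue"] < q_threshold].copy()
    hits = hits.sort_values(["pvalue", "sequence_id", "offset"], kind="mergesort")
    return hits.reset_index(drop=True)[
        ["sequence_id", "offset", "strand", "score", "pvalue", "qvalue", "matched"]
    ]


def palindromicity(theta: np.ndarray) -> float:
    """1 - mean total-variation distance between theta and its reverse
    complement (1.0 = perfect palindrome)."""
    theta = np.asarray(theta, dtype=float)
    rc = theta[::-1, ::-1]
    tv = 0.5 * np.abs(theta - rc).sum(axis=0)
    return float(1.0 - tv.mean())


def information_content(theta: np.ndarray, background: np.ndarray | None = None) -> float:
    """Mean per-column relative entropy of theta vs background, in bits."""
    theta = np.asarray(theta, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(theta > 0, theta * np.log2(theta / bg[:, None]), 0.0)
    return float(terms.sum(axis=0).mean())
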