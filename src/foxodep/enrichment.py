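"""Functional enrichment toolbox.

Covers the downstream interpretation steps of the pipeline:

* one-sided hypergeometric (Fisher) tests for gene-set overlap;
* ontology term enrichment with the *elim* traversal, in which genes of a
  significantly enriched term are removed from its ancestors before the
  ancestors are tested, so enrichment concentrates on the most specific terms;
* the per-term enrichment score ``log2(observed / expected)``;
* selection of the top/bottom quantile tails of protein contributions to a
  principal component;
* position-weight-matrix (PWM) promoter scanning with exact score p-values
  computed by dynamic programming over the discretized log-odds distribution;
* a hypergeometric motif/regulation overlap test restricted to the measured
  protein universe;
* a directional one-sample t-test on the fold changes of a protein set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Ontology",
    "MotifModel",
    "PwmHit",
    "hypergeom_test",
    "elim_fisher",
    "pca_contribution_sets",
    "scan_pwm",
    "motif_overlap_test",
    "direction_test",
]


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


class Ontology:
    """A term DAG with gene annotations and true-path closure.

    Parameters
    ----------
    term_parents:
        Mapping term -> iterable of parent terms.  Terms with no parents are
        roots.  Cycles raise ``ValueError``.
    term_genes:
        Mapping term -> iterable of directly annotated genes.  After
        construction, ``genes(term)`` returns the true-path closure: a gene
        annotated to a term is annotated to all its ancestors.
    """

    def __init__(
        self,
        term_parents: Mapping[str, Iterable[str]],
        term_genes: Mapping[str, Iterable[str]],
    ) -> None:
        terms = set(term_parents) | set(term_genes)
        for parents in term_parents.values():
            terms.update(parents)
        self._parents: dict[str, frozenset[str]] = {
            t: frozenset(term_parents.get(t, ())) for t in terms
        }
        self._children: dict[str, set[str]] = {t: set() for t in terms}
        for t, parents in self._parents.items():
            for p in parents:
                self._children[p].add(t)
        self._direct_genes = {t: frozenset(term_genes.get(t, ())) for t in terms}
        self._order = self._topological_order()
        self._depth = self._compute_depths()
        self._closure = self._compute_closure()

    # -- construction helpers ------------------------------------------------

    def _topological_order(self) -> list[str]:
        """Parents-before-children order; raises on cyclic parent links."""
        indeg = {t: len(self._parents[t]) for t in self._parents}
        queue = sorted(t for t, d in indeg.items() if d == 0)
        order: list[str] = []
        while queue:
            t = queue.pop(0)
            order.append(t)
            for c in sorted(self._children[t]):
                indeg[c] -= 1
                if indeg[c] == 0:
                    queue.append(c)
        if len(order) != len(self._parents):
            raise ValueError("cyclic parent specification in ontology")
        return order

    def _compute_depths(self) -> dict[str, int]:
        depth: dict[str, int] = {}
        for t in self._order:
            parents = self._parents[t]
            depth[t] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth

    def _compute_closure(self) -> dict[str, frozenset[str]]:
        closure: dict[str, frozenset[str]] = {}
        for t in reversed(self._order):
            genes = set(self._direct_genes[t])
            for c in self._children[t]:
                genes |= closure[c]
            closure[t] = frozenset(genes)
        return closure

    # -- queries --------------------------------------------------------------

    @property
    def terms(self) -> list[str]:
        return list(self._order)

    def parents(self, term: str) -> frozenset[str]:
        return self._parents[term]

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._children[term])

    def genes(self, term: str) -> frozenset[str]:
        """True-path-closed gene set of a term."""
        return self._closure[term]

    def depth(self, term: str) -> int:
        """Longest path from a root to the term (roots have depth 0)."""
        return self._depth[term]

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        stack = list(self._parents[term])
        while stack:
            p = stack.pop()
            if p not in out:
                out.add(p)
                stack.extend(self._parents[p])
        return out

    def roots(self) -> list[str]:
        return [t for t in self._order if not self._parents[t]]


# ---------------------------------------------------------------------------
# Hypergeometric overlap test
# ---------------------------------------------------------------------------


def hypergeom_test(k: int, K: int, n: int, N: int) -> float:
    """One-sided over-representation p-value, P(X >= k).

    ``X ~ Hypergeometric(N, K, n)``: from a universe of ``N`` genes of which
    ``K`` carry the annotation, draw ``n``; ``k`` is the observed overlap.
    Identical to a one-sided Fisher exact test on the 2x2 table.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    return float(stats.hypergeom.sf(k - 1, N, K, n))


# ---------------------------------------------------------------------------
# elim-Fisher enrichment
# ---------------------------------------------------------------------------


def elim_fisher(
    ontology: Ontology,
    significant: Iterable[str],
    background: Iterable[str],
    alpha: float = 0.05,
    min_significant: int = 5,
) -> pd.DataFrame:
    """Classic and elim one-sided Fisher enrichment over an ontology.

    Terms are processed bottom-up (deepest DAG level first, lexical order
    within a level).  When a term's elim p-value is <= ``alpha``, its genes
    are removed from every ancestor before the ancestor is tested, so parents
    are only credited with signal their significant descendants do not
    already explain.

    Returns a DataFrame with one row per term intersecting the background:
    annotated and effective gene counts, observed/expected significant
    counts, enrichment score ``log2(observed/expected)``, classic and elim
    p-values, and a flag for the reporting filter of at least
    ``min_significant`` significant genes.
    """
    background = set(background)
    significant = set(significant)
    if not significant <= background:
        missing = sorted(significant - background)[:5]
        raise ValueError(f"significant genes outside background: {missing}")
    n_sig = len(significant)
    n_bg = len(background)

    order = sorted(ontology.terms, key=lambda t: (-ontology.depth(t), t))
    eliminated: dict[str, set[str]] = {t: set() for t in ontology.terms}
    rows = []
    for term in order:
        genes = ontology.genes(term) & background
        if not genes:
            continue
        k = len(genes & significant)
        expected = len(genes) * n_sig / n_bg
        p_classic = hypergeom_test(k, len(genes), n_sig, n_bg)
        genes_eff = genes - eliminated[term]
        if genes_eff:
            k_eff = len(genes_eff & significant)
            p_elim = hypergeom_test(k_eff, len(genes_eff), n_sig, n_bg)
        else:
            k_eff = 0
            p_elim = 1.0
        if p_elim <= alpha:
            for anc in ontology.ancestors(term):
                eliminated[anc] |= genes
        score = math.log2(k / expected) if expected > 0 and k > 0 else -math.inf
        rows.append(
            {
                "term": term,
                "annotated": len(genes),
                "effective": len(genes_eff),
                "observed": k,
                "expected": expected,
                "score": score,
                "p_classic": p_classic,
                "p_elim": p_elim,
                "min_sig_ok": k >= min_significant,
            }
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.sort_values(["p_elim", "term"], kind="mergesort").reset_index(
            drop=True
        )
    return out


# ---------------------------------------------------------------------------
# PCA contribution tails
# ---------------------------------------------------------------------------


def pca_contribution_sets(
    matrix: pd.DataFrame, dimension: int, q: float = 0.05
) -> tuple[pd.Index, pd.Index]:
    """Top and bottom ``q``-quantile tails of protein contributions to a PC.

    The matrix is treated with proteins as observations (rows) and samples as
    variables (columns); columns are centred and the SVD taken.  A protein's
    contribution to dimension ``dimension`` (0-based) is its squared share of
    that component's variance, signed by the side of the axis it falls on.
    The sign convention makes the largest-|score| protein positive.  Ties at
    the median (q = 0.5) go to the bottom set, so the two sets partition the
    proteins.
    """
    if not 0 < q <= 0.5:
        raise ValueError("q must be in (0, 0.5]")
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, _ = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * max(X.shape) * np.finfo(float).eps)) if S.size else 0
    if dimension < 0 or dimension >= rank:
        raise ValueError(f"dimension {dimension} exceeds matrix rank {rank}")
    scores = U[:, dimension] * S[dimension]
    # deterministic orientation of the axis
    if scores[np.argmax(np.abs(scores))] < 0:
        scores = -scores
    contrib = np.sign(scores) * scores**2 / np.sum(scores**2)
    lo = np.quantile(contrib, q)
    hi = np.quantile(contrib, 1.0 - q)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(contrib))
    bottom = index[contrib <= lo]
    top = index[contrib > hi] if hi == lo else index[contrib >= hi]
    return top, bottom


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class MotifModel:
    """Position weight matrix over ACGT with background frequencies.

    ``matrix`` has one row per motif position and columns in A, C, G, T
    order; every row sums to 1.
    """

    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    name: str = "motif"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be width x 4")
        if self.matrix.shape[0] < 4:
            raise ValueError("motif width must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise ValueError("background frequencies must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in np.argmax(self.matrix, axis=1))

    # -- MEME minimal motif format -------------------------------------------

    def to_meme(self, path: str | Path) -> None:
        lines = [
            "MEME version 4",
            "",
            "ALPHABET= ACGT",
            "",
            "strands: + -",
            "",
            "Background letter frequencies",
            " ".join(
                f"{b} {f:.5f}" for b, f in zip(_BASES, self.background)
            ),
            "",
            f"MOTIF {self.name}",
            f"letter-probability matrix: alength= 4 w= {self.width} nsites= 20 E= 0",
        ]
        for row in self.matrix:
            lines.append(" " + " ".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_meme(cls, path: str | Path) -> "MotifModel":
        text = Path(path).read_text().splitlines()
        background = np.full(4, 0.25)
        name = "motif"
        rows: list[list[float]] = []
        i = 0
        while i < len(text):
            line = text[i].strip()
            if line.startswith("Background letter frequencies"):
                parts = text[i + 1].split()
                background = np.array(
                    [float(parts[parts.index(b) + 1]) for b in _BASES]
                )
                i += 1
            elif line.startswith("MOTIF"):
                name = line.split()[1] if len(line.split()) > 1 else name
            elif line.startswith("letter-probability matrix"):
                w = int(line.split("w=")[1].split()[0])
                for j in range(w):
                    rows.append([float(v) for v in text[i + 1 + j].split()])
                i += w
            i += 1
        if not rows:
            raise ValueError(f"no letter-probability matrix found in {path}")
        return cls(matrix=np.array(rows), background=background, name=name)


@dataclass(frozen=True)
class PwmHit:
    start: int  # 0-based, in forward-strand coordinates
    strand: str  # '+' or '-'
    score: float  # log2 odds, discretized
    pvalue: float


def _integer_log_odds(motif: MotifModel, bin_width: float) -> np.ndarray:
    probs = np.clip(motif.matrix, 1e-9, None)
    lo = np.log2(probs / motif.background[None, :])
    return np.round(lo / bin_width).astype(np.int64)


def _score_distribution(ints: np.ndarray, background: np.ndarray):
    """Distribution of the integer score of a background-generated word.

    Returns ``(offset, tail)`` where ``tail[s - offset] = P(S >= s)``.
    """
    dist = np.array([1.0])
    lo_cum = 0
    for j in range(ints.shape[0]):
        col = ints[j]
        cmin = int(col.min())
        new = np.zeros(len(dist) + int(col.max()) - cmin)
        for b in range(4):
            sh = int(col[b]) - cmin
            new[sh : sh + len(dist)] += background[b] * dist
        dist = new
        lo_cum += cmin
    # dist[i] = P(S == lo_cum + i)
    tail = np.cumsum(dist[::-1])[::-1]
    return lo_cum, tail


def _pvalue_lookup(offset: int, tail: np.ndarray):
    def pvalue(score_int: int) -> float:
        idx = score_int - offset
        if idx <= 0:
            return 1.0
        if idx >= len(tail):
            return 0.0
        return float(min(tail[idx], 1.0))

    return pvalue


class _PwmScanner:
    """Precomputed scan tables for one motif (integer log-odds, DP tail)."""

    def __init__(self, motif: MotifModel, p_threshold: float, bin_width: float):
        self.width = motif.width
        self.bin_width = bin_width
        self.ints = _integer_log_odds(motif, bin_width)
        offset, tail = _score_distribution(self.ints, motif.background)
        self.pvalue = _pvalue_lookup(offset, tail)
        # smallest integer score whose tail probability is <= p_threshold;
        # the tail is non-increasing, so one threshold decides all windows
        above = np.nonzero(tail <= p_threshold)[0]
        self.threshold_int = offset + int(above[0]) if above.size else None
        self._base_idx = {c: i for i, c in enumerate("ACGTN")}

    def scan(self, sequence: str) -> list[PwmHit]:
        w = self.width
        seq = sequence.upper()
        if len(seq) < w or self.threshold_int is None:
            return []
        hits: list[PwmHit] = []
        for strand in "+-":
            s = seq if strand == "+" else seq.translate(_COMPLEMENT)[::-1]
            idx = np.array([self._base_idx.get(c, 4) for c in s], dtype=np.int64)
            n_win = len(s) - w + 1
            scores = np.zeros(n_win, dtype=np.int64)
            for j in range(w):
                # N positions score as background (log-ratio 0)
                col = np.append(self.ints[j], 0)
                scores += col[idx[j : j + n_win]]
            for i in np.nonzero(scores >= self.threshold_int)[0]:
                start = int(i) if strand == "+" else len(seq) - w - int(i)
                hits.append(
                    PwmHit(
                        start=start,
                        strand=strand,
                        score=float(scores[i]) * self.bin_width,
                        pvalue=self.pvalue(int(scores[i])),
                    )
                )
        hits.sort(key=lambda h: (h.start, h.strand))
        return hits


def scan_pwm(
    sequence: str,
    motif: MotifModel,
    p_threshold: float = 1e-4,
    bin_width: float = 1e-3,
) -> list[PwmHit]:
    """Scan both strands of a sequence for PWM matches.

    A window is a hit when the probability that a background-generated word
    scores at least as high (the score p-value, computed exactly by dynamic
    programming over the discretized log2-odds distribution) is at or below
    ``p_threshold``.  ``N`` positions contribute a log-odds of 0.  Hit starts
    are 0-based in forward-strand coordinates.
    """
    return _PwmScanner(motif, p_threshold, bin_width).scan(sequence)


def scan_promoters(
    promoters: Mapping[str, str],
    motif: MotifModel,
    p_threshold: float = 1e-4,
    bin_width: float = 1e-3,
) -> pd.DataFrame:
    """Scan many promoters; returns a BED-like table.

    Columns: gene, start, end (0-based, half-open, forward coordinates),
    strand, score, pvalue.
    """
    scanner = _PwmScanner(motif, p_threshold, bin_width)
    rows = []
    for gene in sorted(promoters):
        for h in scanner.scan(promoters[gene]):
            rows.append(
                (gene, h.start, h.start + motif.width, h.strand, h.score, h.pvalue)
            )
    return pd.DataFrame(
        rows, columns=["gene", "start", "end", "strand", "score", "pvalue"]
    )


def pwm_score_pvalues(
    motif: MotifModel, bin_width: float = 1e-3
) -> tuple[int, np.ndarray]:
    """Expose the DP score distribution: ``(offset, tail)`` as in scan_pwm."""
    ints = _integer_log_odds(motif, bin_width)
    return _score_distribution(ints, motif.background)


def score_word(
    word: str, motif: MotifModel, bin_width: float = 1e-3
) -> int:
    """Integer (discretized) log2-odds score of a width-length word."""
    if len(word) != motif.width:
        raise ValueError("word length must equal motif width")
    ints = _integer_log_odds(motif, bin_width)
    total = 0
    for j, c in enumerate(word.upper()):
        total += 0 if c == "N" else int(ints[j, _BASES.index(c)])
    return total


# ---------------------------------------------------------------------------
# Motif / regulation overlap
# ---------------------------------------------------------------------------


def motif_overlap_test(
    genes_with_hits: Iterable[str],
    regulated: Iterable[str],
    background: Iterable[str],
) -> dict:
    """Hypergeometric overlap of motif-carrying and regulated genes.

    Both the selection and the universe are restricted to ``background`` (the
    measured proteins).  Also reports the fraction of regulated genes whose
    promoter carries a motif hit.
    """
    background = set(background)
    hits = set(genes_with_hits) & background
    regulated = set(regulated) & background
    if not regulated:
        raise ValueError("regulated set is empty within the background")
    k = len(hits & regulated)
    p = hypergeom_test(k, len(hits), len(regulated), len(background))
    return {
        "overlap": k,
        "genes_with_hits": len(hits),
        "regulated": len(regulated),
        "background": len(background),
        "fraction": k / len(regulated),
        "pvalue": p,
    }


# ---------------------------------------------------------------------------
# Directional one-sample t-test
# ---------------------------------------------------------------------------


def direction_test(values: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided one-sample t-test of a fold-change set against zero.

    Returns ``(t, p, degenerate)``.  A zero-variance set is degenerate: with
    nonzero mean the p-value is 0 by convention, otherwise (all zeros) t=0,
    p=1; either way the flag is set.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if np.std(arr, ddof=1) == 0:
        if arr.mean() != 0:
            return math.copysign(math.inf, arr.mean()), 0.0, True
        return 0.0, 1.0, True
    res = stats.ttest_1samp(arr, 0.0)
    return float(res.statistic), float(res.pvalue), False
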