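"""PWM scanning against a Markov background and TRE motif enrichment.

Transcription-factor motifs are scored as log-odds (natural log) of the
position probability matrix against a third-order Markov background, with a
fixed hit cutoff of 7.5.  Enrichment of each motif in transcriptionally
*changed* TREs is tested against a GC-content-matched background of
*unchanged* TREs with a one-sided Fisher's exact test and Bonferroni
correction over the motif set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MarkovBackground",
    "MotifModel",
    "EnrichmentResult",
    "scan_motif",
    "has_hit",
    "matched_background",
    "enrichment_test",
    "enrichment_scan",
    "read_meme_motifs",
    "read_tab_pwm",
    "gc_content",
    "LOG_ODDS_CUTOFF",
]

LOG_ODDS_CUTOFF = 7.5  # natural-log log-odds hit threshold
PSEUDOCOUNT = 0.01

_BASE_IDX = np.full(256, -1, dtype=np.int8)
for i, b in enumerate("ACGT"):
    _BASE_IDX[ord(b)] = i
    _BASE_IDX[ord(b.lower())] = i

_COMPLEMENT = {0: 3, 1: 2, 2: 1, 3: 0}


def _encode(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; anything else (N) -> -1."""
    return _BASE_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]


def gc_content(seq: str) -> float:
    enc = _encode(seq)
    valid = enc >= 0
    if not valid.any():
        return 0.0
    return float(np.isin(enc[valid], (1, 2)).mean())


class MarkovBackground:
    """Markov chain over {A,C,G,T} of a given order (default 3).

    Conditional distributions are estimated from a training corpus with
    add-one smoothing; positions with fewer than ``order`` preceding bases
    back off to the longest available context.
    """

    def __init__(self, order: int = 3):
        if order < 0:
            raise ValueError("order must be non-negative")
        self.order = order
        # counts[k] has shape (4**k, 4): context index -> next-base counts
        self._logp: list[np.ndarray] | None = None

    def fit(self, sequences) -> "MarkovBackground":
        counts = [np.ones((4**k, 4)) for k in range(self.order + 1)]
        for seq in sequences:
            enc = _encode(seq)
            n = enc.size
            for k in range(self.order + 1):
                if n <= k:
                    continue
                valid = np.ones(n - k, dtype=bool)
                ctx = np.zeros(n - k, dtype=np.int64)
                for j in range(k):
                    b = enc[j : n - k + j]
                    valid &= b >= 0
                    ctx = ctx * 4 + np.maximum(b, 0)
                nxt = enc[k:]
                valid &= nxt >= 0
                np.add.at(counts[k], (ctx[valid], nxt[valid]), 1)
        self._logp = [np.log(c / c.sum(axis=1, keepdims=True)) for c in counts]
        return self

    def position_logprob(self, enc: np.ndarray) -> np.ndarray:
        """Per-position log background probability of a coded sequence.

        Position i is conditioned on up to ``order`` preceding valid bases;
        N positions get -inf.
        """
        if self._logp is None:
            raise RuntimeError("background not fitted")
        n = enc.size
        out = np.full(n, -np.inf)
        for i in range(n):
            if enc[i] < 0:
                continue
            k = min(self.order, i)
            while k > 0 and (enc[i - k : i] < 0).any():
                k -= 1
            ctx = 0
            for j in range(i - k, i):
                ctx = ctx * 4 + int(enc[j])
            out[i] = self._logp[k][ctx, enc[i]]
        return out

    @classmethod
    def uniform(cls, order: int = 0) -> "MarkovBackground":
        bg = cls(order=order)
        bg._logp = [np.full((4**k, 4), np.log(0.25)) for k in range(order + 1)]
        return bg


@dataclass
class MotifModel:
    """A pseudocounted position probability matrix plus its background."""

    id: str
    ppm: np.ndarray  # L x 4, rows sum to 1
    background: MarkovBackground

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[1] != 4:
            raise ValueError("ppm must be L x 4")
        if not np.allclose(self.ppm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("ppm rows must sum to 1")

    def __len__(self) -> int:
        return self.ppm.shape[0]

    @classmethod
    def from_counts(cls, id, counts, background, pseudocount: float = PSEUDOCOUNT):
        counts = np.asarray(counts, dtype=float) + pseudocount
        return cls(id=id, ppm=counts / counts.sum(axis=1, keepdims=True),
                   background=background)

    @property
    def reverse_complement_ppm(self) -> np.ndarray:
        return self.ppm[::-1, ::-1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.ppm.argmax(axis=1))


def _window_scores(enc: np.ndarray, log_ppm: np.ndarray, bg_logp: np.ndarray) -> np.ndarray:
    """Log-odds score for every offset of a PWM along a coded sequence."""
    L = log_ppm.shape[0]
    n = enc.size
    n_off = n - L + 1
    if n_off <= 0:
        return np.empty(0)
    motif_part = np.zeros(n_off)
    for i in range(L):
        b = enc[i : i + n_off]
        col = np.where(b >= 0, log_ppm[i][np.maximum(b, 0)], -np.inf)
        motif_part = motif_part + col
    csum = np.concatenate(([0.0], np.cumsum(bg_logp)))
    bg_part = csum[L:] - csum[:-L]
    # windows containing N have -inf in both parts; score them -inf outright
    with np.errstate(invalid="ignore"):
        score = motif_part - bg_part
    score[~np.isfinite(motif_part)] = -np.inf
    return score


def scan_motif(seq: str, motif: MotifModel,
               threshold: float = LOG_ODDS_CUTOFF) -> list[tuple[int, str]]:
    """Hit offsets of a motif on both strands of a sequence.

    A window is a hit when the summed natural-log odds
    ``ln(p_motif / p_background)`` reaches the threshold.  The reverse
    strand is scanned with the reverse-complement PPM at the same cutoff;
    windows containing N never score.  Both strands share the forward-strand
    Markov background term (backgrounds are treated as strand-symmetric).
    """
    if len(seq) < len(motif):
        return []
    enc = _encode(seq)
    bg_logp = motif.background.position_logprob(enc)
    hits: list[tuple[int, str]] = []
    with np.errstate(invalid="ignore"):
        fwd = _window_scores(enc, np.log(motif.ppm), bg_logp)
        rev = _window_scores(enc, np.log(motif.reverse_complement_ppm), bg_logp)
    for off in np.flatnonzero(fwd >= threshold):
        hits.append((int(off), "+"))
    for off in np.flatnonzero(rev >= threshold):
        hits.append((int(off), "-"))
    return sorted(hits)


def has_hit(seq: str, motif: MotifModel, threshold: float = LOG_ODDS_CUTOFF) -> bool:
    """Presence/absence of >= 1 hit; same-offset hits on both strands count once."""
    return len({off for off, _ in scan_motif(seq, motif, threshold)}) > 0


def matched_background(changed_gc, unchanged_gc, rng,
                       n_min: int = 1500, bins: int = 20) -> np.ndarray:
    """Indices of a GC-matched sample of unchanged TREs.

    Stratified sampling across GC bins so the background GC histogram
    matches the changed set's relative histogram; total size >= ``n_min``.
    Bins whose demand exceeds the pool borrow from the nearest bins (with a
    warning); an unchanged pool smaller than ``n_min`` is an error.
    """
    changed_gc = np.asarray(changed_gc, dtype=float)
    unchanged_gc = np.asarray(unchanged_gc, dtype=float)
    if unchanged_gc.size < n_min:
        raise ValueError(
            f"unchanged pool ({unchanged_gc.size}) smaller than required "
            f"background size ({n_min})"
        )
    edges = np.linspace(0.0, 1.0, bins + 1)
    c_bin = np.clip(np.digitize(changed_gc, edges) - 1, 0, bins - 1)
    u_bin = np.clip(np.digitize(unchanged_gc, edges) - 1, 0, bins - 1)
    frac = np.bincount(c_bin, minlength=bins) / changed_gc.size
    demand = np.round(frac * n_min).astype(int)
    # rounding drift: top up the largest bins
    while demand.sum() < n_min:
        demand[np.argmax(frac)] += 1
    pool = {b: list(np.flatnonzero(u_bin == b)) for b in range(bins)}
    for b in pool:
        pool[b] = [int(i) for i in rng.permutation(pool[b])]
    picked: list[int] = []
    borrowed = 0
    for b in range(bins):
        need = demand[b]
        take = pool[b][:need]
        picked.extend(take)
        short = need - len(take)
        pool[b] = pool[b][len(take):]
        if short > 0:
            # borrow from nearest bins outward
            for dist in range(1, bins):
                for nb in (b - dist, b + dist):
                    if short == 0 or not (0 <= nb < bins):
                        continue
                    take = pool[nb][:short]
                    picked.extend(take)
                    pool[nb] = pool[nb][len(take):]
                    borrowed += len(take)
                    short -= len(take)
                if short == 0:
                    break
            if short > 0:
                raise ValueError("unchanged pool exhausted during GC matching")
    if borrowed:
        warnings.warn(
            f"GC matching borrowed {borrowed} background TREs from "
            "neighboring GC bins",
            UserWarning,
            stacklevel=2,
        )
    return np.array(sorted(picked), dtype=int)


@dataclass
class EnrichmentResult:
    """One motif's 2x2 enrichment table and Fisher test."""

    motif_id: str
    a: int  # changed with hit
    b: int  # changed without hit
    c: int  # background with hit
    d: int  # background without hit
    odds_ratio: float
    p: float
    p_bonferroni: float

    def as_dict(self) -> dict:
        return {
            "motif_id": self.motif_id, "a": self.a, "b": self.b,
            "c": self.c, "d": self.d, "odds_ratio": self.odds_ratio,
            "p": self.p, "p_bonferroni": self.p_bonferroni,
        }


def enrichment_test(changed_hits, background_hits, motif_id: str = "",
                    n_motifs: int = 1) -> EnrichmentResult:
    """One-sided Fisher's exact test for motif enrichment in changed TREs.

    ``changed_hits`` / ``background_hits`` are boolean has-hit indicators per
    TRE.  The Bonferroni correction multiplies by the size of the motif set
    scanned (the study's motif library holds 622 clustered specificities;
    pass the actual set size).
    """
    ch = np.asarray(changed_hits, dtype=bool)
    bg = np.asarray(background_hits, dtype=bool)
    if ch.size == 0 or bg.size == 0:
        raise ValueError("changed and background sets must be non-empty")
    a, b = int(ch.sum()), int((~ch).sum())
    c, d = int(bg.sum()), int((~bg).sum())
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return EnrichmentResult(
        motif_id=motif_id, a=a, b=b, c=c, d=d,
        odds_ratio=float(odds), p=float(p),
        p_bonferroni=float(min(1.0, p * n_motifs)),
    )


def enrichment_scan(changed_seqs, background_seqs, motifs_list,
                    threshold: float = LOG_ODDS_CUTOFF) -> pd.DataFrame:
    """Scan a motif set over both TRE groups and test each for enrichment."""
    n_motifs = len(motifs_list)
    rows = []
    for motif in motifs_list:
        ch = [has_hit(s, motif, threshold) for s in changed_seqs]
        bg = [has_hit(s, motif, threshold) for s in background_seqs]
        rows.append(enrichment_test(ch, bg, motif.id, n_motifs).as_dict())
    return pd.DataFrame(rows).sort_values("p").reset_index(drop=True)


def read_meme_motifs(path, background: MarkovBackground,
                     pseudocount: float = PSEUDOCOUNT) -> list[MotifModel]:
    """Read motifs from a MEME (minimal) file via Biopython."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        records = bio_motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for b in "ACGT"] for i in range(m.length)])
        mat = mat + pseudocount
        out.append(MotifModel(id=m.name or m.consensus, background=background,
                              ppm=mat / mat.sum(axis=1, keepdims=True)))
    return out


def read_tab_pwm(path, id: str, background: MarkovBackground,
                 pseudocount: float = PSEUDOCOUNT) -> MotifModel:
    """Read a simple whitespace-separated L x 4 probability/count matrix."""
    mat = np.loadtxt(path)
    if mat.ndim == 1:
        mat = mat[None, :]
    return MotifModel.from_counts(id, mat, background, pseudocount=pseudocount)
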