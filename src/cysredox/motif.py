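"""Cysteine-centered sequence windows and pLogo-style binomial enrichment.

Foreground sites are turned into 15-mer windows (cysteine at center, flanks
-7..+7, terminal truncation padded with ``-``).  For each residue r and flank
position j the statistic is the signed -log10 binomial tail probability of
the observed foreground count k against the background frequency p of r at j:
positive values mean enrichment (P(X >= k)), negative values depletion
(P(X <= k)), with exact tail sums rather than a normal approximation.  The
default significance cut-off is the Bonferroni bound over 20 residues x 14
positions at alpha = 0.05, i.e. -log10(0.05/280) = 3.75.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

ALPHABET = tuple("ACDEFGHIKLMNPQRSTVWY")
FLANK = 7
PAD = "-"
#: Flank positions relative to the central cysteine (position 0 excluded).
FLANK_POSITIONS = tuple(j for j in range(-FLANK, FLANK + 1) if j != 0)

#: Default heatmap row order grouped by side-chain property:
#: positively charged, negatively charged, polar uncharged, special, hydrophobic.
PROPERTY_ORDER = tuple("KRHDESTNQCGPAVILMFYW")


def extract_window(db: dict[str, str], accession: str, position: int) -> str:
    """15-mer window centered on the cysteine at 1-based ``position``."""
    seq = db[accession]
    if not 1 <= position <= len(seq) or seq[position - 1] != "C":
        raise ValueError(
            f"{accession} position {position} is not a cysteine "
            f"({seq[position - 1] if 1 <= position <= len(seq) else 'out of range'})"
        )
    i = position - 1
    chars = []
    for j in range(i - FLANK, i + FLANK + 1):
        chars.append(seq[j] if 0 <= j < len(seq) else PAD)
    return "".join(chars)


def all_cysteine_windows(db: dict[str, str]) -> list[str]:
    """Windows for every cysteine in the proteome (the default background)."""
    out = []
    for acc, seq in db.items():
        for i, aa in enumerate(seq):
            if aa == "C":
                out.append(extract_window(db, acc, i + 1))
    return out


def _validate_windows(windows: Sequence[str]) -> None:
    for w in windows:
        if len(w) != 2 * FLANK + 1:
            raise ValueError(f"window {w!r} is not {2 * FLANK + 1} characters")
        if w[FLANK] != "C":
            raise ValueError(f"window {w!r} is not cysteine-centered")


def background_frequencies(
    windows: Sequence[str], mode: str = "per_position"
) -> pd.DataFrame:
    """Per-position residue frequencies p[r][j] over cysteine-centered windows.

    Padding characters are excluded from numerator and denominator.  With
    ``mode="pooled"`` every position gets the pooled flank composition
    instead (the two conventions differ only when composition varies along
    the flank).
    """
    if not windows:
        raise ValueError("empty background")
    _validate_windows(windows)
    counts = pd.DataFrame(0, index=list(ALPHABET), columns=list(FLANK_POSITIONS))
    for w in windows:
        for j in FLANK_POSITIONS:
            aa = w[j + FLANK]
            if aa != PAD:
                counts.loc[aa, j] += 1
    if mode == "pooled":
        pooled = counts.sum(axis=1)
        if pooled.sum() == 0:
            raise ValueError("background has no non-pad residues")
        freq = pooled / pooled.sum()
        return pd.DataFrame({j: freq for j in FLANK_POSITIONS})
    if mode != "per_position":
        raise ValueError(f"unknown background mode {mode!r}")
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        bad = [j for j in FLANK_POSITIONS if totals[j] == 0]
        raise ValueError(f"background positions {bad} have no non-pad residues")
    return counts / totals


def plogo_score(k: int, n: int, p: float) -> float:
    """Signed -log10 binomial tail probability of count ``k`` out of ``n``.

    Enrichment side (k/n >= p): -log10 P(X >= k); depletion side:
    log10 P(X <= k), reported negative.  X ~ Binomial(n, p), exact tails.
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0.0 < p < 1.0:
        raise ValueError(f"degenerate background probability p={p}")
    if n == 0:
        return 0.0
    if k / n >= p:
        tail = float(binom.sf(k - 1, n, p))  # P(X >= k)
        return -math.log10(tail) if tail > 0 else math.inf
    tail = float(binom.cdf(k, n, p))  # P(X <= k)
    return math.log10(tail) if tail > 0 else -math.inf


def significance_threshold(
    alpha: float = 0.05, n_residues: int = 20, n_positions: int = 14
) -> float:
    """Bonferroni-corrected score cut-off: -log10(alpha / (residues x positions))."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside (0, 1]")
    return -math.log10(alpha / (n_residues * n_positions))


@dataclass
class PwmMatrix:
    """Signed binomial score matrix with its supporting counts.

    ``score``/``k``/``p`` are residue x flank-position DataFrames, ``n`` the
    per-position count of foreground windows with a non-pad residue there,
    and ``significant`` holds +1 (enriched above threshold), -1 (depleted
    below -threshold) or 0.
    """

    score: pd.DataFrame
    k: pd.DataFrame
    n: pd.Series
    p: pd.DataFrame
    threshold: float
    significant: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: residue, position, k, n, p, score, significant."""
        rows = []
        for r in self.score.index:
            for j in self.score.columns:
                rows.append(
                    {
                        "residue": r,
                        "position": j,
                        "k": int(self.k.loc[r, j]),
                        "n": int(self.n[j]),
                        "p": float(self.p.loc[r, j]),
                        "score": float(self.score.loc[r, j]),
                        "significant": int(self.significant.loc[r, j]),
                    }
                )
        return pd.DataFrame(rows)


def build_pwm(
    foreground: Sequence[str],
    background: pd.DataFrame | Sequence[str],
    threshold: float | None = None,
) -> PwmMatrix:
    """Score foreground windows against background frequencies.

    ``background`` may be a precomputed frequency matrix or a window list
    (then per-position frequencies are derived from it; the foreground is
    never subtracted).  Cells whose background frequency is exactly 0 or 1
    cannot carry a finite binomial score: k = 0 with p = 0 (or k = n with
    p = 1) scores 0, any other combination scores +/-inf and is flagged.
    """
    if not foreground:
        raise ValueError("empty foreground")
    _validate_windows(foreground)
    if not isinstance(background, pd.DataFrame):
        background = background_frequencies(background)
    if threshold is None:
        threshold = significance_threshold()

    k = pd.DataFrame(0, index=list(ALPHABET), columns=list(FLANK_POSITIONS))
    n = pd.Series(0, index=list(FLANK_POSITIONS))
    for w in foreground:
        for j in FLANK_POSITIONS:
            aa = w[j + FLANK]
            if aa != PAD:
                k.loc[aa, j] += 1
                n[j] += 1

    score = pd.DataFrame(0.0, index=list(ALPHABET), columns=list(FLANK_POSITIONS))
    for r in ALPHABET:
        for j in FLANK_POSITIONS:
            p = float(background.loc[r, j])
            kk, nn = int(k.loc[r, j]), int(n[j])
            if 0.0 < p < 1.0:
                score.loc[r, j] = plogo_score(kk, nn, p)
            elif p == 0.0:
                score.loc[r, j] = 0.0 if kk == 0 else math.inf
            else:  # p == 1
                score.loc[r, j] = 0.0 if kk == nn else -math.inf
    significant = pd.DataFrame(
        np.where(score >= threshold, 1, np.where(score <= -threshold, -1, 0)),
        index=score.index,
        columns=score.columns,
    )
    return PwmMatrix(score=score, k=k, n=n, p=background, threshold=threshold, significant=significant)


def pwm_heatmap_matrix(pwm: PwmMatrix, residue_order: Sequence[str] = PROPERTY_ORDER) -> pd.DataFrame:
    """Reorder the score matrix rows for property-grouped heatmap rendering."""
    if sorted(residue_order) != sorted(ALPHABET):
        raise ValueError("residue_order must be a permutation of the 20-letter alphabet")
    return pwm.score.loc[list(residue_order)]


def plot_pwm_heatmap(pwm: PwmMatrix, residue_order: Sequence[str] = PROPERTY_ORDER, ax=None):
    """Render the property-ordered PWM heatmap (requires matplotlib)."""
    import matplotlib.pyplot as plt

    mat = pwm_heatmap_matrix(pwm, residue_order)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    vmax = float(np.nanmax(np.abs(mat.replace([np.inf, -np.inf], np.nan).values))) or 1.0
    im = ax.imshow(mat.values, cmap="RdBu_r", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(mat.columns)), [f"{j:+d}" for j in mat.columns])
    ax.set_yticks(range(len(mat.index)), mat.index)
    ax.set_xlabel("position relative to cysteine")
    ax.figure.colorbar(im, ax=ax, label="signed -log10 binomial P")
    return ax
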