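"""Monte Carlo expansion of the positive class.

Experimentally confirmed carbonylation sites are far outnumbered by
non-sites, and a classifier trained on the raw benchmark under-calls the
positive class.  The expansion draws additional positive windows position
by position: for each flank position i the empirical residue distribution
p_i over the 21-symbol alphabet (20 amino acids in alphabetical order, X
21st) is estimated from the original positive windows, and each synthetic
window is assembled by inverse-CDF sampling every flank position
independently, with the center fixed at ⊛.  Drawing stops when original
plus synthetic positives reach the target count (normally the size of the
negative subset).

Positions are sampled independently on purpose — the expansion uses only
the per-position marginals even though the feature encoding downstream
models neighbor coupling.  The profile is estimated once from the original
positives and never refit from expanded samples, and expanded samples are
used for training only, never for validation.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from carbonsite.alphabet import ALPHABET, SYNTHETIC_PROTEIN_ID, index_of
from carbonsite.seq_io import POSITIVE_LABEL
from carbonsite.windows import PeptideWindow

N_SYMBOLS = len(ALPHABET)


@dataclass
class PositionalProfile:
    """Per-position residue distributions of the positive class.

    ``probs[i]`` is a length-21 vector over the fixed alphabet order for
    flank position i (i = −ξ…−1, +1…+ξ); each sums to 1.
    """

    xi: int
    center_type: str
    probs: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        expected = [i for i in range(-self.xi, self.xi + 1) if i != 0]
        if sorted(self.probs) != expected:
            raise ValueError("profile must cover every flank position once")
        for i, p in self.probs.items():
            if p.shape != (N_SYMBOLS,) or np.any(p < 0):
                raise ValueError(f"invalid probability vector at position {i}")
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"probabilities at position {i} sum to {p.sum()}, not 1"
                )

    @property
    def positions(self) -> list[int]:
        return [i for i in range(-self.xi, self.xi + 1) if i != 0]


@dataclass
class ExpansionResult:
    """Synthetic positive windows plus provenance."""

    expanded: list[PeptideWindow]
    seed: int
    n_generated: int


def fit_positional_profile(
    positives: Sequence[PeptideWindow],
) -> PositionalProfile:
    """Relative residue frequencies at each flank position of the
    positive windows."""
    if not positives:
        raise ValueError("cannot fit a positional profile from no samples")
    xi = positives[0].xi
    center = positives[0].center_type
    for w in positives:
        if w.xi != xi or w.center_type != center:
            raise ValueError("samples mix flank lengths or center types")
    codes = np.array(
        [[index_of(ch) for ch in w.residues] for w in positives],
        dtype=np.intp,
    )
    n = len(positives)
    probs = {
        pos: np.bincount(codes[:, pos + xi], minlength=N_SYMBOLS) / n
        for pos in range(-xi, xi + 1)
        if pos != 0
    }
    return PositionalProfile(xi=xi, center_type=center, probs=probs)


def draw_residue(profile: PositionalProfile, position: int, r: float) -> str:
    """Map a uniform variate r ∈ [0, 1] to a residue by inverse CDF.

    The k-th alphabet symbol is drawn when the cumulative probability
    through k−1 symbols is ≤ r ≤ the cumulative through k; where r falls
    exactly on a boundary the smaller k wins, which is the standard
    inverse-CDF resolution of the overlapping bounds.
    """
    if position not in profile.probs:
        raise ValueError(f"position {position} not in profile "
                         f"(flank length {profile.xi})")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"r must be in [0, 1], got {r}")
    cum = np.cumsum(profile.probs[position])
    cum[-1] = 1.0  # guard against float round-off at the top
    k = bisect_left(cum, r)
    if k >= N_SYMBOLS:
        k = N_SYMBOLS - 1
    return ALPHABET[k]


def expand_positives(positives: Sequence[PeptideWindow], target_count: int,
                     seed: int) -> ExpansionResult:
    """Generate synthetic positives until the class reaches target_count.

    Each synthetic window draws all 2ξ flank residues independently from
    the positional profile of the original positives; the center is fixed
    at ⊛.  Deterministic for a fixed seed.  Duplicates among draws are
    allowed.  Downsampling is out of scope: target_count below the current
    count is an error.
    """
    n_original = len(positives)
    if target_count < n_original:
        raise ValueError(
            f"target_count {target_count} is below the current positive "
            f"count {n_original}; expansion never discards samples"
        )
    n_new = target_count - n_original
    if n_new == 0:
        return ExpansionResult(expanded=[], seed=seed, n_generated=0)
    profile = fit_positional_profile(positives)
    xi = profile.xi
    rng = np.random.default_rng(seed)
    expanded: list[PeptideWindow] = []
    for idx in range(n_new):
        rs = rng.random(2 * xi)
        flanks = [
            draw_residue(profile, pos, rs[j])
            for j, pos in enumerate(profile.positions)
        ]
        residues = "".join(flanks[:xi]) + profile.center_type + "".join(flanks[xi:])
        expanded.append(
            PeptideWindow(
                residues=residues,
                center_type=profile.center_type,
                protein_id=SYNTHETIC_PROTEIN_ID,
                center_position=idx + 1,
                label=POSITIVE_LABEL,
                synthetic=True,
            )
        )
    return ExpansionResult(expanded=expanded, seed=seed, n_generated=n_new)
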