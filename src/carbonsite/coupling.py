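"""Sequence-coupled conditional-probability encoding.

Each flank position of a window contributes one feature: the probability of
the residue observed there, estimated from the positive training subset,
minus the same probability estimated from the negative subset.  For the
positions adjacent to the center (−1 and +1) the probability is
unconditional (their inner neighbor is always the center residue ⊛); every
other position is conditioned on its inner neighbor — upstream positions on
the residue to their right, downstream positions on the residue to their
left.  With flank length ξ = 7 the encoding is a 14-dimensional vector,
each component in [−1, 1].

Probabilities are raw relative frequencies by default; an optional additive
smoothing α spreads mass over the 21-symbol alphabet for tiny training
sets.  When a conditioning residue was never observed at a position (and
α = 0) the lookup falls back per a configurable policy: "marginal"
substitutes the position's unconditional distribution, "zero" contributes
nothing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from carbonsite.alphabet import ALPHABET, CENTER_TYPES, index_of
from carbonsite.errors import SelfConsistencyError
from carbonsite.windows import PeptideWindow

N_SYMBOLS = len(ALPHABET)  # 21

FALLBACK_POLICIES = ("marginal", "zero")

FORMAT_VERSION = 1


def flank_positions(xi: int) -> list[int]:
    """Flank positions in vector order: −ξ … −1, +1 … +ξ."""
    return list(range(-xi, 0)) + list(range(1, xi + 1))


def _neighbor(position: int) -> int | None:
    """Inner-neighbor position a conditional table conditions on, or None
    for the unconditional positions ±1."""
    if position in (-1, 1):
        return None
    return position + 1 if position < 0 else position - 1


@dataclass
class ConditionalProfile:
    """Position-specific probability tables for one training subset.

    ``conditional[i]`` is a 21×21 array indexed ``[b, a]`` holding
    P(residue a at position i | residue b at the inner-neighbor position);
    rows with no observed support are all-zero and flagged in
    ``support[i]``.  ``marginal[i]`` is the unconditional distribution of
    position i (the feature itself at ±1, the fallback elsewhere).
    """

    xi: int
    conditional: dict[int, np.ndarray]
    marginal: dict[int, np.ndarray]
    support: dict[int, np.ndarray]
    alpha: float = 0.0
    n_samples: int = 0

    @property
    def positions(self) -> list[int]:
        return flank_positions(self.xi)

    def probability(self, position: int, residue: str, neighbor: str | None,
                    fallback_policy: str = "marginal") -> float:
        """Look up p_i(residue | neighbor), applying the fallback policy
        when the conditioning residue is unsupported."""
        a = index_of(residue)
        if _neighbor(position) is None:
            return float(self.marginal[position][a])
        if neighbor is None:
            raise ValueError(f"position {position} requires a neighbor residue")
        b = index_of(neighbor)
        if self.support[position][b]:
            return float(self.conditional[position][b, a])
        if fallback_policy == "marginal":
            return float(self.marginal[position][a])
        if fallback_policy == "zero":
            return 0.0
        raise ValueError(f"unknown fallback policy {fallback_policy!r}")


def fit_profile(samples: Sequence[PeptideWindow],
                alpha: float = 0.0) -> ConditionalProfile:
    """Estimate a conditional profile from windows of one class.

    Conditional entries are ``(count(a, b) + α) / (count(b) + 21α)`` where
    counts are taken over the sample windows at the relevant position pair;
    marginals are ``(count(a) + α) / (n + 21α)``.
    """
    if not samples:
        raise ValueError("cannot fit a profile from an empty sample list")
    if alpha < 0:
        raise ValueError(f"alpha must be >= 0, got {alpha}")
    xi = samples[0].xi
    center = samples[0].center_type
    for w in samples:
        if w.xi != xi or w.center_type != center:
            raise ValueError("samples mix flank lengths or center types")

    # integer-code all windows: column j <-> position offset j - xi
    codes = np.array(
        [[index_of(ch) for ch in w.residues] for w in samples], dtype=np.intp
    )
    n = len(samples)

    conditional: dict[int, np.ndarray] = {}
    marginal: dict[int, np.ndarray] = {}
    support: dict[int, np.ndarray] = {}
    for pos in flank_positions(xi):
        col = codes[:, pos + xi]
        counts = np.bincount(col, minlength=N_SYMBOLS).astype(float)
        marginal[pos] = (counts + alpha) / (n + N_SYMBOLS * alpha)
        nb = _neighbor(pos)
        if nb is None:
            continue
        nb_col = codes[:, nb + xi]
        joint = np.zeros((N_SYMBOLS, N_SYMBOLS))
        np.add.at(joint, (nb_col, col), 1.0)
        row_totals = joint.sum(axis=1)
        support[pos] = (row_totals > 0) | (alpha > 0)
        denom = row_totals + N_SYMBOLS * alpha
        table = np.zeros_like(joint)
        nonzero = denom > 0
        table[nonzero] = (joint[nonzero] + alpha) / denom[nonzero, None]
        conditional[pos] = table
    return ConditionalProfile(xi=xi, conditional=conditional,
                              marginal=marginal, support=support,
                              alpha=alpha, n_samples=n)


@dataclass
class CouplingModel:
    """Paired positive/negative conditional profiles for one center type."""

    positive_profile: ConditionalProfile
    negative_profile: ConditionalProfile
    center_type: str
    xi: int
    alpha: float = 0.0
    fallback_policy: str = "marginal"

    def __post_init__(self) -> None:
        if self.center_type not in CENTER_TYPES:
            raise ValueError(f"unknown center type {self.center_type!r}")
        if self.fallback_policy not in FALLBACK_POLICIES:
            raise ValueError(
                f"fallback_policy must be one of {FALLBACK_POLICIES}, "
                f"got {self.fallback_policy!r}"
            )
        if (self.positive_profile.xi != self.xi
                or self.negative_profile.xi != self.xi):
            raise ValueError("profiles disagree with the model's xi")

    @property
    def n_features(self) -> int:
        return 2 * self.xi

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format_version": FORMAT_VERSION,
            "alphabet": ALPHABET,
            "center_type": self.center_type,
            "xi": self.xi,
            "alpha": self.alpha,
            "fallback_policy": self.fallback_policy,
            "profiles": {
                name: _profile_to_dict(profile)
                for name, profile in (
                    ("positive", self.positive_profile),
                    ("negative", self.negative_profile),
                )
            },
        }
        text = json.dumps(doc)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "CouplingModel":
        if isinstance(source, Path):
            text = source.read_text()
        elif str(source).lstrip().startswith("{"):
            text = str(source)
        else:
            text = Path(str(source)).read_text()
        doc = json.loads(text)
        if doc.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported coupling-model format version "
                f"{doc.get('format_version')!r} (expected {FORMAT_VERSION})"
            )
        if doc["alphabet"] != ALPHABET:
            raise ValueError("coupling model uses a different alphabet order")
        profiles = {
            name: _profile_from_dict(doc["profiles"][name], doc["xi"],
                                     doc["alpha"])
            for name in ("positive", "negative")
        }
        return cls(
            positive_profile=profiles["positive"],
            negative_profile=profiles["negative"],
            center_type=doc["center_type"],
            xi=doc["xi"],
            alpha=doc["alpha"],
            fallback_policy=doc["fallback_policy"],
        )


def _profile_to_dict(profile: ConditionalProfile) -> dict:
    return {
        "n_samples": profile.n_samples,
        "marginal": {str(i): v.tolist() for i, v in profile.marginal.items()},
        "conditional": {str(i): v.tolist()
                        for i, v in profile.conditional.items()},
        "support": {str(i): v.astype(int).tolist()
                    for i, v in profile.support.items()},
    }


def _profile_from_dict(doc: dict, xi: int, alpha: float) -> ConditionalProfile:
    return ConditionalProfile(
        xi=xi,
        conditional={int(i): np.asarray(v)
                     for i, v in doc["conditional"].items()},
        marginal={int(i): np.asarray(v) for i, v in doc["marginal"].items()},
        support={int(i): np.asarray(v, dtype=bool)
                 for i, v in doc["support"].items()},
        alpha=alpha,
        n_samples=doc["n_samples"],
    )


def fit_coupling_model(train, alpha: float = 0.0,
                       fallback_policy: str = "marginal") -> CouplingModel:
    """Fit positive and negative profiles from a training sample set."""
    if not train.positives or not train.negatives:
        raise ValueError("both subsets must be non-empty to fit a model")
    return CouplingModel(
        positive_profile=fit_profile(train.positives, alpha),
        negative_profile=fit_profile(train.negatives, alpha),
        center_type=train.center_type,
        xi=train.xi,
        alpha=alpha,
        fallback_policy=fallback_policy,
    )


def encode(window: PeptideWindow, model: CouplingModel,
           fallback_policy: str | None = None) -> np.ndarray:
    """Encode a window as the positive-minus-negative probability vector.

    Component order follows the flank positions −ξ … −1, +1 … +ξ; the
    center residue contributes no component (it is fixed by construction).
    """
    if window.center_type != model.center_type:
        raise SelfConsistencyError(
            f"a {window.center_type}-centered window cannot be encoded by a "
            f"{model.center_type}-trained model"
        )
    if window.xi != model.xi:
        raise ValueError(
            f"window flank length {window.xi} != model flank length {model.xi}"
        )
    policy = fallback_policy or model.fallback_policy
    xi = model.xi
    vec = np.empty(2 * xi)
    for k, pos in enumerate(flank_positions(xi)):
        residue = window.residues[pos + xi]
        nb = _neighbor(pos)
        neighbor = window.residues[nb + xi] if nb is not None else None
        vec[k] = (
            model.positive_profile.probability(pos, residue, neighbor, policy)
            - model.negative_profile.probability(pos, residue, neighbor, policy)
        )
    return vec


def encode_many(windows: Sequence[PeptideWindow], model: CouplingModel,
                fallback_policy: str | None = None) -> np.ndarray:
    """Stack encodings of many windows into an (n, 2ξ) matrix."""
    if not windows:
        return np.empty((0, 2 * model.xi))
    return np.vstack([encode(w, model, fallback_policy) for w in windows])
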