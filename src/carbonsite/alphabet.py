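"""The 21-symbol residue alphabet shared by every module.

The 20 native amino acids in alphabetical single-letter order, followed by
the dummy residue X used to pad windows that run past a sequence terminus.
X is a full 21st symbol everywhere: in positional profiles, in conditional
probability tables, and in identity computations.
"""

from __future__ import annotations

# Alphabetical order of the native amino acids; X is the 21st symbol.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWYX"
AA20: str = ALPHABET[:20]

#: Residue types prone to carbonylation; each gets its own model.
CENTER_TYPES: str = "KPRT"

#: Symbol -> index into the fixed alphabet order.
ALPHABET_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(ALPHABET)}

#: Sentinel protein id carried by Monte-Carlo-expanded windows.
SYNTHETIC_PROTEIN_ID: str = "__synthetic__"


def index_of(symbol: str) -> int:
    """Return the alphabet index of ``symbol``, rejecting anything else."""
    try:
        return ALPHABET_INDEX[symbol]
    except KeyError:
        raise ValueError(
            f"residue {symbol!r} is not one of the 20 amino acids or X"
        ) from None
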