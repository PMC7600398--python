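"""Canonical ordering and label handling for the 96 single-base-substitution classes.

The SBS96 classification crosses the six pyrimidine-centered substitutions
(C>A, C>G, C>T, T>A, T>C, T>G) with the four possible bases on each side of
the mutated base.  The canonical order used throughout this package is
substitution-major with flanks alphabetical, i.e. the order COSMIC signature
files use: ``A[C>A]A, A[C>A]C, ..., T[T>G]T``.
"""

from __future__ import annotations

SUBSTITUTIONS: tuple[str, ...] = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES: tuple[str, ...] = ("A", "C", "G", "T")
N_TYPES = 96

_SUB_RANK = {s: i for i, s in enumerate(SUBSTITUTIONS)}
_BASE_RANK = {b: i for i, b in enumerate(BASES)}


class MutationTypeError(ValueError):
    """Raised when a mutation-type token cannot be interpreted."""


def mutation_type_index(substitution: str, left: str, right: str) -> int:
    """Map a (substitution, 5' flank, 3' flank) triple to its canonical index.

    The index is ``16 * rank(substitution) + 4 * rank(left) + rank(right)``
    with substitutions ordered C>A < C>G < C>T < T>A < T>C < T>G and bases
    ordered alphabetically, so ``A[C>A]A`` is 0 and ``T[T>G]T`` is 95.
    """
    try:
        s = _SUB_RANK[substitution]
    except KeyError:
        raise MutationTypeError(
            f"unknown substitution class {substitution!r}; expected one of "
            f"{', '.join(SUBSTITUTIONS)}"
        ) from None
    try:
        l = _BASE_RANK[left]
    except KeyError:
        raise MutationTypeError(f"5' flanking base {left!r} is not one of A/C/G/T") from None
    try:
        r = _BASE_RANK[right]
    except KeyError:
        raise MutationTypeError(f"3' flanking base {right!r} is not one of A/C/G/T") from None
    return 16 * s + 4 * l + r


def mutation_type_from_index(index: int) -> tuple[str, str, str]:
    """Inverse of :func:`mutation_type_index`."""
    if not 0 <= index < N_TYPES:
        raise MutationTypeError(f"mutation-type index {index} outside [0, 95]")
    s, rem = divmod(index, 16)
    l, r = divmod(rem, 4)
    return SUBSTITUTIONS[s], BASES[l], BASES[r]


def format_label(substitution: str, left: str, right: str) -> str:
    """Render a triple in the conventional bracket notation, e.g. ``A[T>C]G``."""
    mutation_type_index(substitution, left, right)  # validate
    return f"{left}[{substitution}]{right}"


def parse_label(label: str) -> tuple[str, str, str]:
    """Parse ``A[T>C]G`` or ``T>C,A,G`` style mutation-type labels.

    Returns the (substitution, left flank, right flank) triple; raises
    :class:`MutationTypeError` for anything else.
    """
    token = label.strip()
    if "[" in token:
        try:
            left, rest = token.split("[", 1)
            sub, right = rest.split("]", 1)
        except ValueError:
            raise MutationTypeError(f"malformed mutation-type label {label!r}") from None
    else:
        parts = [p.strip() for p in token.split(",")]
        if len(parts) != 3:
            raise MutationTypeError(f"malformed mutation-type label {label!r}")
        sub, left, right = parts
    mutation_type_index(sub, left, right)  # validate, raising with the bad token
    return sub, left, right


def label_index(label: str) -> int:
    """Canonical index of a mutation-type label in either accepted style."""
    return mutation_type_index(*parse_label(label))


#: All 96 labels in canonical order.
MUTATION_TYPES: tuple[str, ...] = tuple(
    format_label(*mutation_type_from_index(i)) for i in range(N_TYPES)
)
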