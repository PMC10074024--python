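"""Haplotype templates: patterns over the alphabet {'0', '1', 'X'}.

A template describes a (possibly non-contiguous) haplotype in a region of
``u`` biallelic SNPs.  At each position '0' requires the reference allele,
'1' the alternative allele, and 'X' matches either.  The four-SNP template
``"1XX0"`` therefore encodes an interaction between the first and fourth
SNP only.  The number of non-'X' characters is the template's *order*.

The all-'X' pattern is excluded everywhere: it matches every haplotype and
is indistinguishable from the model intercept.  An unconstrained region of
``u`` SNPs consequently yields ``3**u - 1`` templates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, product
from typing import Iterable, Sequence

__all__ = [
    "FeatureSetSpec",
    "template_order",
    "validate_template",
    "canonical_key",
    "canonical_sort",
    "enumerate_templates",
    "matches",
    "extend_templates",
]

_ALPHABET = frozenset("01X")


def template_order(pattern: str) -> int:
    """Number of fixed (non-'X') positions of a template."""
    return len(pattern) - pattern.count("X")


def validate_template(pattern: str) -> str:
    """Check a template string and return it unchanged.

    Raises ``ValueError`` for characters outside {0,1,X}, empty patterns,
    or the all-'X' pattern (which is the intercept, not a feature).
    """
    if not pattern:
        raise ValueError("empty template pattern")
    bad = set(pattern) - _ALPHABET
    if bad:
        raise ValueError(f"invalid template characters {sorted(bad)!r} in {pattern!r}")
    if template_order(pattern) == 0:
        raise ValueError("the all-'X' template is the intercept and is not a feature")
    return pattern


def canonical_key(pattern: str) -> tuple[int, str]:
    """Sort key for the canonical template order.

    Ascending order (number of fixed positions) first, then lexicographic
    with '0' < '1' < 'X' (plain ASCII order).  Deterministic canonical
    identity lets candidate models be deduplicated across CV replicates.
    """
    return (template_order(pattern), pattern)


def canonical_sort(patterns: Iterable[str]) -> list[str]:
    """Deduplicate and sort templates into the canonical order."""
    return sorted(set(patterns), key=canonical_key)


@dataclass(frozen=True)
class FeatureSetSpec:
    """Constraint on which templates are enumerated for a region.

    Parameters
    ----------
    max_order
        Maximum number of SNPs allowed to interact in one template
        (``None`` = unbounded, the "all_hap" set).  ``1`` reproduces the
        single-SNP set, ``2`` the "2SNP_hap" set, and so on.
    htr_only
        If True, only full-order templates with no 'X' are generated —
        classic haplotype trend regression (HTR).
    """

    max_order: int | None = None
    htr_only: bool = False

    def __post_init__(self) -> None:
        if self.max_order is not None and self.max_order < 1:
            raise ValueError("max_order must be >= 1")

    @classmethod
    def from_string(cls, spec: str) -> "FeatureSetSpec":
        """Parse "1", "2", ..., "all" or "htr" into a spec."""
        s = str(spec).strip().lower()
        if s == "all":
            return cls()
        if s == "htr":
            return cls(htr_only=True)
        return cls(max_order=int(s))

    def label(self) -> str:
        if self.htr_only:
            return "HTR"
        if self.max_order is None:
            return "all_hap"
        if self.max_order == 1:
            return "SNP"
        return f"{self.max_order}SNP_hap"


def enumerate_templates(u: int, spec: FeatureSetSpec | None = None) -> list[str]:
    """Enumerate every template of a ``u``-SNP region allowed by ``spec``.

    Returns templates in canonical order with no duplicates and without
    the all-'X' pattern.  The unconstrained count is ``3**u - 1``; with a
    maximum order ``K`` it is ``sum(C(u,m) * 2**m for m in 1..K)``.
    """
    if u < 1:
        raise ValueError("region must contain at least one SNP")
    if spec is None:
        spec = FeatureSetSpec()
    if spec.htr_only:
        pats = ["".join(p) for p in product("01", repeat=u)]
        return canonical_sort(pats)
    k = u if spec.max_order is None else min(spec.max_order, u)
    if k > u:
        raise ValueError(f"max_order {k} exceeds region size {u}")
    pats: list[str] = []
    base = ["X"] * u
    for m in range(1, k + 1):
        for pos in combinations(range(u), m):
            for alleles in product("01", repeat=m):
                pat = base.copy()
                for p, a in zip(pos, alleles):
                    pat[p] = a
                pats.append("".join(pat))
    return canonical_sort(pats)


def matches(haplotype: str, template: str) -> bool:
    """True iff ``haplotype`` carries ``template``.

    Every fixed position of the template must equal the haplotype allele;
    'X' positions are unconstrained.
    """
    if len(haplotype) != len(template):
        raise ValueError(
            f"haplotype length {len(haplotype)} != template length {len(template)}"
        )
    if set(haplotype) - {"0", "1"}:
        raise ValueError(f"haplotype must be binary, got {haplotype!r}")
    return all(t == "X" or h == t for h, t in zip(haplotype, template))


def extend_templates(retained: Sequence[str], new_snp_index: int) -> list[str]:
    """Grow a retained template set by one additional SNP.

    Each retained pattern is extended at ``new_snp_index`` with '0', '1'
    and 'X', and the two fresh single-SNP templates at that position are
    added, giving exactly ``3*M + 2`` candidates for ``M`` distinct
    inputs.  Two calling conventions are supported:

    * ``new_snp_index == len(pattern)``: patterns grow by one character
      (building a region left to right);
    * ``new_snp_index < len(pattern)``: the position must currently be
      'X' in every retained pattern and is substituted in place (patterns
      pre-padded to the full region width).

    The output is canonically sorted and deduplicated (deduplication never
    triggers when the inputs are distinct and none covers the new SNP).
    """
    retained = list(retained)
    if not retained:
        raise ValueError("retained template set must be non-empty")
    width = len(retained[0])
    if any(len(t) != width for t in retained):
        raise ValueError("retained templates must share one width")
    if new_snp_index == width:
        out = [t + a for t in retained for a in "01X"]
        out += ["X" * width + a for a in "01"]
    elif 0 <= new_snp_index < width:
        if any(t[new_snp_index] != "X" for t in retained):
            raise ValueError(
                f"SNP {new_snp_index} already covered by a retained template"
            )
        out = []
        for t in retained:
            for a in "01X":
                out.append(t[:new_snp_index] + a + t[new_snp_index + 1 :])
        blank = ["X"] * width
        for a in "01":
            blank[new_snp_index] = a
            out.append("".join(blank))
    else:
        raise ValueError(f"new_snp_index {new_snp_index} out of range for width {width}")
    return canonical_sort(out)
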