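"""Star-allele diplotype parsing and metabolizer-phenotype translation.

CYP2C19 and CYP2D6 diplotypes (e.g. ``*1/*2``, ``*1/*1x2``, ``*36+*10/*4``)
are parsed into a canonical :class:`Diplotype` and translated into
metabolizer phenotypes following the CPIC convention: a function-class pair
lookup for CYP2C19 (normal / intermediate / poor / rapid / ultrarapid) and a
copy-number-aware activity score for CYP2D6 (poor / intermediate / normal /
ultrarapid).

Allele function assignments live in a TSV table shipped with the package
(:func:`load_allele_definitions`); phenotype bin edges for the CYP2D6
activity score are configurable through :class:`PhenotypeBinConfig`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "Gene",
    "FunctionClass",
    "Phenotype",
    "AlleleDefinition",
    "AlleleTable",
    "Diplotype",
    "PhenotypeCall",
    "PhenotypeBinConfig",
    "DiplotypeParseError",
    "IndeterminateAllele",
    "load_allele_definitions",
    "parse_diplotype",
    "activity_score",
    "call_phenotype",
    "altered",
]


class Gene(str, Enum):
    CYP2C19 = "CYP2C19"
    CYP2D6 = "CYP2D6"


class FunctionClass(str, Enum):
    NORMAL = "normal"
    DECREASED = "decreased"
    NO_FUNCTION = "no_function"
    INCREASED = "increased"
    UNCERTAIN = "uncertain"


class Phenotype(str, Enum):
    PM = "PM"
    IM = "IM"
    NM = "NM"
    RM = "RM"  # CYP2C19 only
    UM = "UM"
    INDETERMINATE = "Indeterminate"


#: Ordering of determinate phenotypes from least to most enzyme activity.
PHENOTYPE_ORDER = {
    Phenotype.PM: 0,
    Phenotype.IM: 1,
    Phenotype.NM: 2,
    Phenotype.RM: 3,
    Phenotype.UM: 4,
}


class DiplotypeParseError(ValueError):
    """Raised when a diplotype string does not match the expected grammar."""


class IndeterminateAllele(KeyError):
    """Raised when an allele is unknown or has uncertain function.

    Callers translating to phenotypes catch this and emit an
    ``Indeterminate`` call rather than failing.
    """


@dataclass(frozen=True)
class AlleleDefinition:
    """Function assignment for one star allele of one gene.

    ``activity_value`` is the per-copy CYP2D6 activity-score contribution
    (1.0 normal, 0.25/0.5 decreased, 0 no-function); it is ``None`` for
    CYP2C19 alleles and for uncertain-function alleles, where no score is
    defined.
    """

    gene: Gene
    name: str
    function_class: FunctionClass
    activity_value: float | None = None

    def __post_init__(self) -> None:
        if self.activity_value is not None:
            if self.activity_value < 0:
                raise ValueError(f"negative activity_value for {self.name}")
            zero = self.activity_value == 0
            nofunc = self.function_class is FunctionClass.NO_FUNCTION
            if zero != nofunc:
                raise ValueError(
                    f"{self.gene.value} {self.name}: activity_value must be 0 "
                    "exactly when function_class is no_function"
                )
        if (
            self.function_class is FunctionClass.INCREASED
            and self.gene is not Gene.CYP2C19
        ):
            raise ValueError(
                f"increased function is only defined for CYP2C19 (got {self.name} "
                f"for {self.gene.value})"
            )


class AlleleTable:
    """Indexed set of :class:`AlleleDefinition`, unique per (gene, allele)."""

    def __init__(self, definitions: Iterable[AlleleDefinition]):
        self._defs: dict[tuple[Gene, str], AlleleDefinition] = {}
        for d in definitions:
            key = (d.gene, d.name)
            if key in self._defs:
                raise ValueError(f"duplicate allele {d.name} for {d.gene.value}")
            self._defs[key] = d

    def get(self, gene: Gene, allele: str) -> AlleleDefinition | None:
        return self._defs.get((gene, allele))

    def require(self, gene: Gene, allele: str) -> AlleleDefinition:
        d = self.get(gene, allele)
        if d is None:
            raise IndeterminateAllele(f"unknown {gene.value} allele {allele!r}")
        if d.function_class is FunctionClass.UNCERTAIN:
            raise IndeterminateAllele(
                f"{gene.value} allele {allele!r} has uncertain function"
            )
        return d

    def alleles(self, gene: Gene) -> list[str]:
        return [name for (g, name) in self._defs if g is gene]

    def __len__(self) -> int:
        return len(self._defs)


_ALLELE_RE = re.compile(r"^\*\w+$")


def _numeric_key(allele: str) -> tuple[int, str]:
    """Sort key: numeric part of the (first) star allele, then the label."""
    m = re.match(r"\*(\d+)", allele)
    return (int(m.group(1)) if m else 10**9, allele)


@dataclass(frozen=True, order=False)
class Diplotype:
    """A parsed pair of star alleles with copy numbers, in canonical order.

    Hybrid tandem haplotypes (``*36+*10``) are kept as a single allele unit
    whose name joins the components with ``+``; the allele table carries a
    dedicated entry for the tandem.
    """

    gene: Gene
    allele1: str
    copy1: int
    allele2: str
    copy2: int
    raw: str = ""

    def __post_init__(self) -> None:
        if self.copy1 < 1 or self.copy2 < 1:
            raise ValueError("copy numbers must be positive")
        # enforce canonical ordering so *2/*1 and *1/*2 compare equal
        k1, k2 = _numeric_key(self.allele1), _numeric_key(self.allele2)
        if (k1, self.copy1) > (k2, self.copy2):
            a1, c1 = self.allele1, self.copy1
            object.__setattr__(self, "allele1", self.allele2)
            object.__setattr__(self, "copy1", self.copy2)
            object.__setattr__(self, "allele2", a1)
            object.__setattr__(self, "copy2", c1)

    def __str__(self) -> str:
        def side(a: str, c: int) -> str:
            return f"{a}x{c}" if c > 1 else a

        return f"{side(self.allele1, self.copy1)}/{side(self.allele2, self.copy2)}"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Diplotype):
            return NotImplemented
        return (self.gene, self.allele1, self.copy1, self.allele2, self.copy2) == (
            other.gene,
            other.allele1,
            other.copy1,
            other.allele2,
            other.copy2,
        )

    def __hash__(self) -> int:
        return hash((self.gene, self.allele1, self.copy1, self.allele2, self.copy2))


def _parse_haplotype(token: str, raw: str) -> tuple[str, int]:
    """Parse one side of a diplotype: ``allele[xN](+allele)*``."""
    if not token:
        raise DiplotypeParseError(f"empty allele token in {raw!r}")
    units = token.split("+")
    first = units[0]
    copy = 1
    m = re.match(r"^(?P<allele>\*\w+?)x(?P<n>-?\d+)$", first)
    if m:
        first = m.group("allele")
        copy = int(m.group("n"))
        if copy < 1:
            raise DiplotypeParseError(
                f"copy number must be a positive integer in {first + 'x' + m.group('n')!r}"
            )
    for u in [first] + units[1:]:
        if not _ALLELE_RE.match(u):
            raise DiplotypeParseError(f"malformed allele token {u!r} in {raw!r}")
    name = "+".join([first] + units[1:])
    return name, copy


def parse_diplotype(text: str, gene: Gene | str) -> Diplotype:
    """Parse a diplotype string like ``*1/*2``, ``*1/*1x2`` or ``*36+*10/*4``.

    The two haplotypes are separated by ``/``; ``xN`` multiplies the copy
    number of a haplotype and ``+`` joins the components of a hybrid tandem.
    Canonical ordering (lower star number first) is applied, so
    ``parse_diplotype("*2/*1", g) == parse_diplotype("*1/*2", g)``.

    Raises :class:`DiplotypeParseError` on malformed input, naming the
    offending token.
    """
    gene = Gene(gene)
    if not text or not text.strip():
        raise DiplotypeParseError("empty diplotype string")
    raw = text.strip()
    sides = raw.split("/")
    if len(sides) != 2:
        raise DiplotypeParseError(
            f"expected exactly one '/' separating two haplotypes in {raw!r}"
        )
    a1, c1 = _parse_haplotype(sides[0].strip(), raw)
    a2, c2 = _parse_haplotype(sides[1].strip(), raw)
    return Diplotype(gene=gene, allele1=a1, copy1=c1, allele2=a2, copy2=c2, raw=raw)


@dataclass(frozen=True)
class PhenotypeBinConfig:
    """CYP2D6 activity-score bin edges (CPIC convention).

    score = 0 -> PM; 0 < score <= ``im_max`` -> IM;
    ``im_max`` < score <= ``nm_max`` -> NM; score > ``nm_max`` -> UM.
    """

    im_max: float = 1.0
    nm_max: float = 2.25

    def bin(self, score: float) -> Phenotype:
        if score < 0:
            raise ValueError("activity score cannot be negative")
        if score == 0:
            return Phenotype.PM
        if score <= self.im_max:
            return Phenotype.IM
        if score <= self.nm_max:
            return Phenotype.NM
        return Phenotype.UM


DEFAULT_BINS = PhenotypeBinConfig()


@dataclass(frozen=True)
class PhenotypeCall:
    """Metabolizer phenotype assigned to one diplotype.

    ``activity_score`` is set only for determinate CYP2D6 calls.
    """

    gene: Gene
    phenotype: Phenotype
    source_diplotype: Diplotype
    activity_score: float | None = None

    def __post_init__(self) -> None:
        if self.phenotype is Phenotype.RM and self.gene is not Gene.CYP2C19:
            raise ValueError("rapid metabolizer (RM) is defined for CYP2C19 only")
        has_score = self.activity_score is not None
        should_have = (
            self.gene is Gene.CYP2D6 and self.phenotype is not Phenotype.INDETERMINATE
        )
        if has_score != should_have:
            raise ValueError(
                "activity_score must be present exactly for determinate CYP2D6 calls"
            )


def activity_score(d: Diplotype, defs: AlleleTable) -> float:
    """CYP2D6 activity score: sum of per-allele activity values times copies.

    Raises :class:`IndeterminateAllele` if either allele is unknown or of
    uncertain function.
    """
    if d.gene is not Gene.CYP2D6:
        raise ValueError("activity scores are defined for CYP2D6 only")
    total = 0.0
    for allele, copies in ((d.allele1, d.copy1), (d.allele2, d.copy2)):
        definition = defs.require(Gene.CYP2D6, allele)
        assert definition.activity_value is not None
        total += definition.activity_value * copies
    return total


def _cyp2c19_phenotype(f1: FunctionClass, f2: FunctionClass) -> Phenotype:
    classes = sorted((f1.value, f2.value))
    n_nofunc = sum(f is FunctionClass.NO_FUNCTION for f in (f1, f2))
    if n_nofunc == 2:
        return Phenotype.PM
    if n_nofunc == 1:
        # includes no_function/increased, which CPIC calls intermediate
        return Phenotype.IM
    if FunctionClass.DECREASED in (f1, f2):
        # decreased/normal, decreased/decreased, decreased/increased
        return Phenotype.IM
    if classes == ["normal", "normal"]:
        return Phenotype.NM
    if classes == ["increased", "normal"]:
        return Phenotype.RM
    if classes == ["increased", "increased"]:
        return Phenotype.UM
    raise AssertionError(f"unhandled CYP2C19 function pair {classes}")


def call_phenotype(
    d: Diplotype,
    defs: AlleleTable,
    bins: PhenotypeBinConfig = DEFAULT_BINS,
) -> PhenotypeCall:
    """Translate a diplotype to a metabolizer phenotype.

    CYP2D6 calls bin the activity score; CYP2C19 calls use the
    function-class pair lookup. Unknown or uncertain-function alleles yield
    an ``Indeterminate`` call rather than an error.
    """
    try:
        if d.gene is Gene.CYP2D6:
            score = activity_score(d, defs)
            return PhenotypeCall(
                gene=d.gene,
                phenotype=bins.bin(score),
                activity_score=score,
                source_diplotype=d,
            )
        f1 = defs.require(Gene.CYP2C19, d.allele1).function_class
        f2 = defs.require(Gene.CYP2C19, d.allele2).function_class
        return PhenotypeCall(
            gene=d.gene,
            phenotype=_cyp2c19_phenotype(f1, f2),
            source_diplotype=d,
        )
    except IndeterminateAllele:
        return PhenotypeCall(
            gene=d.gene, phenotype=Phenotype.INDETERMINATE, source_diplotype=d
        )


def altered(call: PhenotypeCall) -> bool:
    """True iff the phenotype is determinate and non-normal.

    Indeterminate calls are conservatively treated as not altered so they
    never enter actionability or consistency numerators.
    """
    return call.phenotype not in (Phenotype.NM, Phenotype.INDETERMINATE)


def load_allele_definitions(path: str | Path | None = None) -> AlleleTable:
    """Load the allele function table (TSV: gene, allele, function_class,
    activity_value). Defaults to the table shipped with the package."""
    if path is None:
        ref = resources.files("pgxeval.data").joinpath("allele_definitions.tsv")
        text = ref.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    defs: list[AlleleDefinition] = []
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    expected = ["gene", "allele", "function_class", "activity_value"]
    if header != expected:
        raise ValueError(f"allele table header must be {expected}, got {header}")
    for ln in lines[1:]:
        fields = ln.split("\t")
        if len(fields) == 3:  # trailing blank activity_value column omitted
            fields.append("")
        if len(fields) != 4:
            raise ValueError(f"malformed allele table row: {ln!r}")
        gene, allele, fclass, value = (f.strip() for f in fields)
        defs.append(
            AlleleDefinition(
                gene=Gene(gene),
                name=allele,
                function_class=FunctionClass(fclass),
                activity_value=float(value) if value else None,
            )
        )
    return AlleleTable(defs)
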