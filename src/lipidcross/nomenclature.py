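"""Shorthand lipid nomenclature: parsing, validation, canonical formatting.

Shotgun lipidomics reports species in a compact text grammar.  A *sum
species* gives only the summed chain composition after the class code,
``PC 34:1;0`` — 34 carbons, 1 double bond, 0 hydroxylations across all
chains.  A *subspecies* resolves the individual chains, separated by ``_``
when the sn-position on the glycerol backbone is unknown
(``PI 18:1;0_16:0;0``) or by ``/`` when it is resolved
(``PC O-18:1;0/16:0;0``).  Ether lipid classes carry the ``O-`` marker in
the class code; their first resolved chain is an alkyl ether rather than an
ester-bound acyl chain.  The trailing ``;h`` hydroxylation count is written
``;0`` for glycerophospholipids but is frequently omitted by third-party
exports, so an absent suffix is read as 0.

The module also defines the fixed 14-class plasma taxonomy used throughout
the package (sterols, glycerolipids, glycerophospholipids and their lyso
and ether forms, sphingolipids).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

__all__ = [
    "ChainKind",
    "Level",
    "Category",
    "ChainAnnotation",
    "SpeciesAnnotation",
    "ClassEntry",
    "ClassTaxonomy",
    "NomenclatureError",
    "LipidParseError",
    "TaxonomyError",
    "ChainValidationError",
    "parse_species",
    "format_species",
    "taxonomy",
    "validate_names",
]


class NomenclatureError(ValueError):
    """Base class for all lipid-name errors."""


class LipidParseError(NomenclatureError):
    """The text does not follow the shorthand grammar."""


class TaxonomyError(NomenclatureError):
    """The class code is not one of the 14 known classes."""


class ChainValidationError(NomenclatureError):
    """A chain or total violates carbon/double-bond/hydroxylation bounds."""


class ChainKind(str, Enum):
    ACYL = "acyl"
    ALKYL_ETHER = "alkyl_ether"


class Level(str, Enum):
    SUM_SPECIES = "sum_species"
    SUBSPECIES = "subspecies"


class Category(str, Enum):
    STEROL = "sterol"
    GLYCEROLIPID = "glycerolipid"
    GLYCEROPHOSPHOLIPID = "glycerophospholipid"
    LYSOPHOSPHOLIPID = "lysophospholipid"
    SPHINGOLIPID = "sphingolipid"


@dataclass(frozen=True)
class ChainAnnotation:
    """One hydrocarbon chain: ``C:DB;OH`` with an acyl/alkyl-ether kind."""

    kind: ChainKind
    carbons: int
    double_bonds: int
    hydroxylations: int = 0

    def __post_init__(self) -> None:
        if self.carbons < 1:
            raise ChainValidationError(
                f"chain carbons must be >= 1, got {self.carbons}"
            )
        if not 0 <= self.double_bonds < self.carbons:
            raise ChainValidationError(
                f"double bonds must satisfy 0 <= DB < C, got "
                f"{self.double_bonds} for {self.carbons} carbons"
            )
        if not 0 <= self.hydroxylations <= self.carbons:
            raise ChainValidationError(
                f"hydroxylations must satisfy 0 <= OH <= C, got "
                f"{self.hydroxylations} for {self.carbons} carbons"
            )

    @property
    def key(self) -> str:
        """The ``C:DB;OH`` text key, e.g. ``18:1;0``."""
        return f"{self.carbons}:{self.double_bonds};{self.hydroxylations}"


@dataclass(frozen=True)
class SpeciesAnnotation:
    """A fully parsed lipid species or subspecies annotation.

    ``raw_name`` records the input verbatim and does not participate in
    equality; two annotations parsed from ``PC 34:1`` and ``PC 34:1;0``
    compare equal.
    """

    raw_name: str = field(compare=False)
    lipid_class: str
    level: Level
    chains: tuple[ChainAnnotation, ...]
    sn_resolved: bool
    total_carbons: int
    total_double_bonds: int
    total_hydroxylations: int

    def __post_init__(self) -> None:
        if self.sn_resolved and self.level is not Level.SUBSPECIES:
            raise ChainValidationError("sn_resolved requires subspecies level")
        if self.level is Level.SUBSPECIES and self.chains:
            sums = (
                sum(c.carbons for c in self.chains),
                sum(c.double_bonds for c in self.chains),
                sum(c.hydroxylations for c in self.chains),
            )
            totals = (
                self.total_carbons,
                self.total_double_bonds,
                self.total_hydroxylations,
            )
            if sums != totals:
                raise ChainValidationError(
                    f"totals {totals} do not match chain sums {sums}"
                )

    @property
    def canonical_name(self) -> str:
        return format_species(self)


@dataclass(frozen=True)
class ClassEntry:
    code: str
    full_name: str
    category: Category


class ClassTaxonomy(Sequence):
    """The fixed, ordered 14-class plasma lipid taxonomy."""

    def __init__(self, entries: Iterable[ClassEntry]):
        self._entries = tuple(entries)
        self._by_code = {e.code: e for e in self._entries}
        if len(self._by_code) != len(self._entries):
            raise TaxonomyError("class codes must be unique")

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[ClassEntry]:
        return iter(self._entries)

    def __contains__(self, code: object) -> bool:
        return code in self._by_code

    def __getitem__(self, key):
        if isinstance(key, str):
            try:
                return self._by_code[key]
            except KeyError:
                raise TaxonomyError(f"unknown lipid class code: {key!r}") from None
        return self._entries[key]

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(e.code for e in self._entries)


_TAXONOMY = ClassTaxonomy(
    [
        ClassEntry("Chol", "cholesterol", Category.STEROL),
        ClassEntry("CE", "cholesterol ester", Category.STEROL),
        ClassEntry("TAG", "triacylglycerol", Category.GLYCEROLIPID),
        ClassEntry("DAG", "diacylglycerol", Category.GLYCEROLIPID),
        ClassEntry("PC", "phosphatidylcholine", Category.GLYCEROPHOSPHOLIPID),
        ClassEntry("PC O-", "phosphatidylcholine ether", Category.GLYCEROPHOSPHOLIPID),
        ClassEntry("PE", "phosphatidylethanolamine", Category.GLYCEROPHOSPHOLIPID),
        ClassEntry(
            "PE O-", "phosphatidylethanolamine ether", Category.GLYCEROPHOSPHOLIPID
        ),
        ClassEntry("PI", "phosphatidylinositol", Category.GLYCEROPHOSPHOLIPID),
        ClassEntry("LPC", "lysophosphatidylcholine", Category.LYSOPHOSPHOLIPID),
        ClassEntry(
            "LPC O-", "lysophosphatidylcholine ether", Category.LYSOPHOSPHOLIPID
        ),
        ClassEntry("LPE", "lysophosphatidylethanolamine", Category.LYSOPHOSPHOLIPID),
        ClassEntry("SM", "sphingomyelin", Category.SPHINGOLIPID),
        ClassEntry("Cer", "ceramide", Category.SPHINGOLIPID),
    ]
)

# The ceramide class appears both as "CER" (class listings) and "Cer"
# (figure legends); both map onto the single code Cer.
_CLASS_ALIASES = {"CER": "Cer"}

# Ether class codes, longest first so "LPC O-" wins over "LPC".
_ETHER_CLASSES = ("LPC O-", "PC O-", "PE O-")

# Maximum number of resolved chains the grammar accepts (TAG).
_MAX_CHAINS = 3

_CHAIN_RE = re.compile(r"^(O-)?(\d+):(\d+)(?:;(\d+))?$")


def taxonomy() -> ClassTaxonomy:
    """Return the fixed 14-entry class taxonomy in its canonical order."""
    return _TAXONOMY


def _split_class(name: str) -> tuple[str, str]:
    """Split a normalized name into (class code, chain block text)."""
    for code in _ETHER_CLASSES:
        stem = code[:-2].rstrip()  # "PC O-" -> "PC"
        m = re.match(rf"^{stem} O-\s*(\S.*)$", name)
        if m:
            return code, m.group(1)
    head, _, rest = name.partition(" ")
    head = _CLASS_ALIASES.get(head, head)
    return head, rest.strip()


def _parse_chain(token: str, kind: ChainKind) -> ChainAnnotation:
    m = _CHAIN_RE.match(token)
    if m is None:
        raise LipidParseError(f"cannot parse chain token {token!r}")
    has_o = m.group(1) is not None
    if has_o:
        kind = ChainKind.ALKYL_ETHER
    return ChainAnnotation(
        kind=kind,
        carbons=int(m.group(2)),
        double_bonds=int(m.group(3)),
        hydroxylations=int(m.group(4) or 0),
    )


def parse_species(name: str) -> SpeciesAnnotation:
    """Parse a shorthand lipid name into a :class:`SpeciesAnnotation`.

    Raises :class:`LipidParseError` for text outside the grammar,
    :class:`TaxonomyError` for an unknown class code, and
    :class:`ChainValidationError` when the annotation violates chain bounds
    (e.g. more double bonds than carbons).
    """
    if not isinstance(name, str) or not name.strip():
        raise LipidParseError("empty lipid name")
    normalized = re.sub(r"\s+", " ", name.strip())

    cls, block = _split_class(normalized)
    if cls not in _TAXONOMY:
        raise TaxonomyError(f"unknown lipid class code in {name!r}: {cls!r}")

    if not block:
        if cls != "Chol":
            raise LipidParseError(f"class {cls!r} requires a chain block: {name!r}")
        return SpeciesAnnotation(
            raw_name=name,
            lipid_class="Chol",
            level=Level.SUM_SPECIES,
            chains=(),
            sn_resolved=False,
            total_carbons=0,
            total_double_bonds=0,
            total_hydroxylations=0,
        )
    if cls == "Chol":
        raise LipidParseError(f"cholesterol carries no chain annotation: {name!r}")

    if "/" in block and "_" in block:
        raise LipidParseError(f"mixed '/' and '_' separators in {name!r}")
    sn_resolved = "/" in block
    tokens = re.split(r"[/_]", block)
    if len(tokens) > _MAX_CHAINS:
        raise LipidParseError(
            f"at most {_MAX_CHAINS} chains supported, got {len(tokens)}: {name!r}"
        )

    is_ether = cls.endswith("O-")
    if len(tokens) == 1:
        # A single C:DB;OH block after the class code is a sum species; the
        # totals are the block itself and no individual chains are resolved.
        total = _parse_chain(tokens[0], ChainKind.ACYL)
        if total.kind is ChainKind.ALKYL_ETHER and not is_ether:
            raise LipidParseError(
                f"'O-' chain marker outside an ether class: {name!r}"
            )
        return SpeciesAnnotation(
            raw_name=name,
            lipid_class=cls,
            level=Level.SUM_SPECIES,
            chains=(),
            sn_resolved=False,
            total_carbons=total.carbons,
            total_double_bonds=total.double_bonds,
            total_hydroxylations=total.hydroxylations,
        )

    chains = []
    for i, token in enumerate(tokens):
        # In ether classes the O- marker travels with the class code, so the
        # first chain is the alkyl ether.
        kind = ChainKind.ALKYL_ETHER if (is_ether and i == 0) else ChainKind.ACYL
        chain = _parse_chain(token, kind)
        if chain.kind is ChainKind.ALKYL_ETHER and not (is_ether and i == 0):
            raise LipidParseError(
                f"'O-' chain marker outside an ether class sn-1 position: {name!r}"
            )
        chains.append(chain)

    return SpeciesAnnotation(
        raw_name=name,
        lipid_class=cls,
        level=Level.SUBSPECIES,
        chains=tuple(chains),
        sn_resolved=sn_resolved,
        total_carbons=sum(c.carbons for c in chains),
        total_double_bonds=sum(c.double_bonds for c in chains),
        total_hydroxylations=sum(c.hydroxylations for c in chains),
    )


def format_species(annotation: SpeciesAnnotation) -> str:
    """Render the canonical text form; ``parse_species`` round-trips it."""
    cls = annotation.lipid_class
    if cls == "Chol":
        return "Chol"
    # Ether class codes glue directly onto the chain block: "PC O-34:1;0".
    prefix = cls if cls.endswith("O-") else cls + " "
    if annotation.level is Level.SUM_SPECIES:
        block = (
            f"{annotation.total_carbons}:{annotation.total_double_bonds}"
            f";{annotation.total_hydroxylations}"
        )
        return prefix + block
    sep = "/" if annotation.sn_resolved else "_"
    tokens = []
    for i, chain in enumerate(annotation.chains):
        tok = chain.key
        if chain.kind is ChainKind.ALKYL_ETHER and not (cls.endswith("O-") and i == 0):
            tok = "O-" + tok
        tokens.append(tok)
    return prefix + sep.join(tokens)


def validate_names(names: Iterable[str]) -> tuple[list[SpeciesAnnotation], dict[str, str]]:
    """Batch-validate names; returns (parsed annotations, {name: error})."""
    parsed: list[SpeciesAnnotation] = []
    errors: dict[str, str] = {}
    for raw in names:
        try:
            parsed.append(parse_species(raw))
        except NomenclatureError as exc:
            errors[raw] = f"{type(exc).__name__}: {exc}"
    return parsed, errors
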