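"""Reaction records, condition vocabularies, and dataset I/O.

The data model mirrors a curated photocatalysis reaction database: each record
holds a reaction SMILES (components separated by ``.``, reactant and product
sides separated by ``>>`` — the typographic ``»`` is accepted on input), an
optional set of reaction conditions in five categories (photocatalyst, base or
acid, additive, wavelength, solvent), and optional metadata (time in hours,
yield in percent, literature reference).

Conditions are stored on records as *common names*; a :class:`ConditionVocabulary`
maps names to compact category-prefixed tokens (``P3``, ``B31``, ...) used as
model inputs. Index 0 in every category means "None" (condition absent), so a
record without an added base still carries the explicit token ``B0``.
Reactions that need no external photosensitizer carry the photocatalyst label
``autocatalysis``.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "CATEGORIES",
    "CATEGORY_PREFIXES",
    "PREFIX_TO_CATEGORY",
    "ChemistryParseError",
    "ReactionFormatError",
    "UnknownReagentError",
    "DatasetFormatError",
    "Molecule",
    "ConditionToken",
    "ConditionNames",
    "ConditionSet",
    "ConditionVocabulary",
    "ReactionRecord",
    "DatasetStats",
    "canonicalize",
    "parse_reaction",
    "render_reaction",
    "parse_condition_token",
    "normalize_condition_name",
    "build_vocabulary",
    "encode_conditions",
    "decode_conditions",
    "read_dataset",
    "write_dataset",
    "dataset_stats",
    "load_synonyms",
    "default_synonyms",
]

#: The five condition categories, in the fixed ordering used everywhere
#: (token injection order, condition-target order, report order).
CATEGORIES: tuple[str, ...] = (
    "photocatalyst",
    "base_or_acid",
    "additive",
    "wavelength",
    "solvent",
)

#: One-letter token prefixes per category (mnemonic: P, B, A, W, S).
CATEGORY_PREFIXES: dict[str, str] = {
    "photocatalyst": "P",
    "base_or_acid": "B",
    "additive": "A",
    "wavelength": "W",
    "solvent": "S",
}

PREFIX_TO_CATEGORY: dict[str, str] = {v: k for k, v in CATEGORY_PREFIXES.items()}

NONE_NAME = "None"


class ChemistryParseError(ValueError):
    """A SMILES string could not be parsed by the chemistry toolkit."""


class ReactionFormatError(ValueError):
    """A reaction SMILES violates the one-separator / no-empty-component format."""


class UnknownReagentError(KeyError):
    """A condition name is absent from the vocabulary and synonym dictionary."""


class DatasetFormatError(ValueError):
    """A dataset file is malformed; the message carries the line number."""


# ---------------------------------------------------------------------------
# molecules and reactions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Molecule:
    """A molecule as a SMILES string, flagged if in canonical form."""

    smiles: str
    canonical: bool = False

    def canonicalized(self) -> "Molecule":
        return canonicalize(self.smiles) if not self.canonical else self


def canonicalize(smiles: str) -> Molecule:
    """Return the canonical form of ``smiles``.

    Canonicalization is idempotent: re-canonicalizing the output returns the
    same string. Raises :class:`ChemistryParseError` naming the offending
    input when the string is not valid SMILES.
    """
    if not smiles:
        raise ChemistryParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryParseError(f"unparsable SMILES: {smiles!r}")
    return Molecule(Chem.MolToSmiles(mol), canonical=True)


def canonical_components(text: str) -> tuple[str, ...]:
    """Canonicalize a '.'-separated multi-component SMILES, order-insensitively.

    Used as the equality key behind accuracy metrics: two multi-component
    strings match iff their canonical component multisets match.
    """
    return tuple(sorted(canonicalize(part).smiles for part in text.split(".")))


_SEPARATORS = ("»", ">>")


def parse_reaction(reaction_smiles: str) -> tuple[list[str], list[str]]:
    """Split a reaction SMILES into (reactants, products) component lists.

    Accepts both the ``»`` typography and the standard ``>>`` dialect; exactly
    one separator must be present, and no component may be empty.
    """
    text = reaction_smiles.strip()
    sep = "»" if "»" in text else ">>"
    n_sep = text.count("»") + text.count(">>")
    if n_sep == 0:
        raise ReactionFormatError(f"no reactant/product separator in {text!r}")
    if n_sep > 1:
        raise ReactionFormatError(f"multiple separators in {text!r}")
    left, right = text.split(sep)
    sides = []
    for side, label in ((left, "reactant"), (right, "product")):
        parts = side.split(".")
        if not side or any(not p for p in parts):
            raise ReactionFormatError(f"empty {label} component in {text!r}")
        sides.append(parts)
    return sides[0], sides[1]


def render_reaction(reactants: Sequence[str], products: Sequence[str]) -> str:
    """Render a reaction SMILES with ``.`` between components and ``>>``."""
    return ".".join(reactants) + ">>" + ".".join(products)


# ---------------------------------------------------------------------------
# condition tokens and vocabulary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConditionToken:
    """A compact category-prefixed condition identifier, e.g. ``B31``."""

    category: str
    index: int

    def __post_init__(self) -> None:
        if self.category not in CATEGORY_PREFIXES:
            raise ValueError(f"unknown condition category {self.category!r}")
        if self.index < 0:
            raise ValueError("condition index must be non-negative")

    @property
    def token(self) -> str:
        return f"{CATEGORY_PREFIXES[self.category]}{self.index}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.token


def parse_condition_token(text: str) -> ConditionToken:
    """Parse ``"B31"`` back into a :class:`ConditionToken` (round trip)."""
    if not text or text[0] not in PREFIX_TO_CATEGORY or not text[1:].isdigit():
        raise ValueError(f"not a condition token: {text!r}")
    return ConditionToken(PREFIX_TO_CATEGORY[text[0]], int(text[1:]))


@dataclass(frozen=True)
class ConditionNames:
    """Named reaction conditions; ``None`` in a field means condition absent."""

    photocatalyst: str | None = None
    base_or_acid: str | None = None
    additive: str | None = None
    wavelength: str | None = None
    solvent: str | None = None

    def get(self, category: str) -> str | None:
        return getattr(self, category)

    def as_dict(self) -> dict[str, str | None]:
        return {c: getattr(self, c) for c in CATEGORIES}


@dataclass(frozen=True)
class ConditionSet:
    """One :class:`ConditionToken` per category — always all five present."""

    tokens: tuple[ConditionToken, ...]

    def __post_init__(self) -> None:
        if tuple(t.category for t in self.tokens) != CATEGORIES:
            raise ValueError("a ConditionSet needs one token per category, in order")

    def token_strings(self) -> list[str]:
        return [t.token for t in self.tokens]

    def get(self, category: str) -> ConditionToken:
        return self.tokens[CATEGORIES.index(category)]

    @classmethod
    def from_strings(cls, strings: Sequence[str]) -> "ConditionSet":
        return cls(tuple(parse_condition_token(s) for s in strings))


def _normkey(name: str) -> str:
    """Case- and whitespace-insensitive matching key for reagent names."""
    return "".join(name.split()).lower()


class ConditionVocabulary:
    """Per-category bijective map between common names and token indices.

    Index 0 is reserved for ``"None"`` in every category. A synonym dictionary
    (raw name -> canonical common name) is consulted before lookup, and all
    matching is case- and whitespace-insensitive.
    """

    def __init__(self, synonyms: Mapping[str, str] | None = None) -> None:
        self._name_to_index: dict[str, dict[str, int]] = {}
        self._index_to_name: dict[str, dict[int, str]] = {}
        for cat in CATEGORIES:
            self._name_to_index[cat] = {_normkey(NONE_NAME): 0}
            self._index_to_name[cat] = {0: NONE_NAME}
        self.synonyms: dict[str, str] = {}
        if synonyms:
            for raw, canon in synonyms.items():
                self.synonyms[_normkey(raw)] = canon

    # -- construction ------------------------------------------------------

    def add(self, category: str, name: str) -> ConditionToken:
        """Register ``name`` in ``category`` (idempotent); return its token."""
        if category not in CATEGORY_PREFIXES:
            raise ValueError(f"unknown condition category {category!r}")
        key = _normkey(name)
        table = self._name_to_index[category]
        if key not in table:
            index = len(table)
            table[key] = index
            self._index_to_name[category][index] = name
        return ConditionToken(category, table[key])

    def add_synonym(self, raw: str, canonical: str) -> None:
        self.synonyms[_normkey(raw)] = canonical

    # -- lookup ------------------------------------------------------------

    def normalize(self, raw: str | None, category: str | None = None) -> str:
        """Map a raw reagent name to its canonical common name.

        The synonym dictionary is consulted first; failing that, the name must
        itself be a registered canonical name. ``None`` normalizes to "None".
        """
        if raw is None:
            return NONE_NAME
        key = _normkey(raw)
        if key in self.synonyms:
            return self.synonyms[key]
        cats = [category] if category else list(CATEGORIES)
        for cat in cats:
            idx = self._name_to_index[cat].get(key)
            if idx is not None:
                return self._index_to_name[cat][idx]
        raise UnknownReagentError(
            f"unknown reagent name {raw!r} (searched categories: {', '.join(cats)})"
        )

    def index_of(self, category: str, name: str | None) -> int:
        canon = self.normalize(name, category)
        idx = self._name_to_index[category].get(_normkey(canon))
        if idx is None:
            raise UnknownReagentError(
                f"name {canon!r} not in category {category!r}"
            )
        return idx

    def name_of(self, category: str, index: int) -> str:
        try:
            return self._index_to_name[category][index]
        except KeyError:
            raise UnknownReagentError(
                f"index {index} not in category {category!r}"
            ) from None

    def names(self, category: str) -> list[str]:
        """All canonical names in a category, by index order (incl. "None")."""
        table = self._index_to_name[category]
        return [table[i] for i in range(len(table))]

    def size(self, category: str) -> int:
        return len(self._index_to_name[category])

    def token(self, category: str, name: str | None) -> ConditionToken:
        return ConditionToken(category, self.index_of(category, name))

    def decode_token(self, token: ConditionToken) -> str | None:
        name = self.name_of(token.category, token.index)
        return None if name == NONE_NAME else name

    def condition_token_strings(self) -> list[str]:
        """Every renderable condition token (``P0``..``S*``), for model vocabularies."""
        out = []
        for cat in CATEGORIES:
            out.extend(ConditionToken(cat, i).token for i in range(self.size(cat)))
        return out


def normalize_condition_name(
    raw: str, vocab: ConditionVocabulary, category: str | None = None
) -> str:
    """Normalize a raw reagent name via the vocabulary's synonym dictionary."""
    return vocab.normalize(raw, category)


def encode_conditions(names: ConditionNames, vocab: ConditionVocabulary) -> ConditionSet:
    """Encode named conditions into the five-token :class:`ConditionSet`."""
    return ConditionSet(
        tuple(vocab.token(cat, names.get(cat)) for cat in CATEGORIES)
    )


def decode_conditions(cs: ConditionSet, vocab: ConditionVocabulary) -> ConditionNames:
    """Inverse of :func:`encode_conditions` for in-vocabulary names."""
    return ConditionNames(**{
        cat: vocab.decode_token(cs.get(cat)) for cat in CATEGORIES
    })


def build_vocabulary(
    records: Iterable["ReactionRecord"],
    synonyms: Mapping[str, str] | None = None,
) -> ConditionVocabulary:
    """Build a vocabulary from records, indexing names by first appearance.

    Deterministic for a fixed record order; index 0 is "None" in every
    category even for an empty input.
    """
    vocab = ConditionVocabulary(synonyms)
    for rec in records:
        if rec.conditions is None:
            continue
        for cat in CATEGORIES:
            name = rec.conditions.get(cat)
            if name is not None:
                vocab.add(cat, name)
    return vocab


# ---------------------------------------------------------------------------
# records and datasets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReactionRecord:
    """One literature (or synthetic) photocatalytic reaction.

    ``conditions is None`` marks a record outside the condition-annotated
    subset; a record *with* conditions always has all five categories
    resolved (``None`` fields meaning "condition absent", token index 0).
    """

    reactants: tuple[Molecule, ...]
    products: tuple[Molecule, ...]
    conditions: ConditionNames | None = None
    time_h: float | None = None
    yield_pct: float | None = None
    reference: str | None = None

    def __post_init__(self) -> None:
        if not self.reactants or not self.products:
            raise ValueError("reactant and product lists must be non-empty")

    @property
    def reaction_smiles(self) -> str:
        return render_reaction(
            [m.smiles for m in self.reactants], [m.smiles for m in self.products]
        )

    def canonical_reaction(self) -> str:
        """Order-insensitive canonical reaction key (for novelty indexing)."""
        r = sorted(m.canonicalized().smiles for m in self.reactants)
        p = sorted(m.canonicalized().smiles for m in self.products)
        return render_reaction(r, p)

    @classmethod
    def from_smiles(
        cls,
        reaction_smiles: str,
        conditions: ConditionNames | None = None,
        time_h: float | None = None,
        yield_pct: float | None = None,
        reference: str | None = None,
        validate: bool = True,
    ) -> "ReactionRecord":
        reactants, products = parse_reaction(reaction_smiles)
        if validate:
            for s in (*reactants, *products):
                canonicalize(s)
        return cls(
            tuple(Molecule(s) for s in reactants),
            tuple(Molecule(s) for s in products),
            conditions,
            time_h,
            yield_pct,
            reference,
        )


@dataclass(frozen=True)
class DatasetStats:
    """Composition counts of a reaction dataset.

    ``n_multicomponent`` counts reactions with >= 3 reactant components;
    per-category distinct-name counts exclude the "None" placeholder.
    """

    n_total: int
    n_multicomponent: int
    n_three_component: int
    n_four_component: int
    n_with_conditions: int
    distinct_names: dict[str, int] = field(default_factory=dict)

    @property
    def multicomponent_fraction(self) -> float:
        return self.n_multicomponent / self.n_total if self.n_total else math.nan

    def as_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_multicomponent": self.n_multicomponent,
            "n_three_component": self.n_three_component,
            "n_four_component": self.n_four_component,
            "n_with_conditions": self.n_with_conditions,
            "distinct_names": dict(self.distinct_names),
        }


def dataset_stats(records: Sequence[ReactionRecord]) -> DatasetStats:
    """Composition counts: totals, multicomponent splits, per-category names."""
    n_multi = n_three = n_four = n_cond = 0
    names: dict[str, set[str]] = {c: set() for c in CATEGORIES}
    for rec in records:
        k = len(rec.reactants)
        if k >= 3:
            n_multi += 1
        if k == 3:
            n_three += 1
        elif k == 4:
            n_four += 1
        if rec.conditions is not None:
            n_cond += 1
            for cat in CATEGORIES:
                name = rec.conditions.get(cat)
                if name is not None and name != NONE_NAME:
                    names[cat].add(name)
    return DatasetStats(
        n_total=len(records),
        n_multicomponent=n_multi,
        n_three_component=n_three,
        n_four_component=n_four,
        n_with_conditions=n_cond,
        distinct_names={c: len(v) for c, v in names.items()},
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_FIELDS = (
    "reaction",
    "photocatalyst",
    "base_or_acid",
    "additive",
    "wavelength",
    "solvent",
    "time_h",
    "yield_pct",
    "reference",
)

#: Marks a record whose conditions are entirely unannotated (outside the
#: condition subset), as opposed to annotated-as-absent (all "None").
_NO_CONDITIONS = "__none__"


def _record_to_row(rec: ReactionRecord) -> dict:
    row: dict = {"reaction": rec.reaction_smiles}
    if rec.conditions is None:
        for cat in CATEGORIES:
            row[cat] = _NO_CONDITIONS
    else:
        for cat in CATEGORIES:
            row[cat] = rec.conditions.get(cat)
    row["time_h"] = rec.time_h
    row["yield_pct"] = rec.yield_pct
    row["reference"] = rec.reference
    return row


def _row_to_record(row: Mapping, lineno: int, validate: bool) -> ReactionRecord:
    def clean(v):
        if v is None or v == "" or v == _NO_CONDITIONS:
            return None
        return v

    cond_values = {cat: row.get(cat) for cat in CATEGORIES}
    if all(v == _NO_CONDITIONS or v is None for v in cond_values.values()) and any(
        v == _NO_CONDITIONS for v in cond_values.values()
    ):
        conditions = None
    else:
        conditions = ConditionNames(**{
            cat: clean(cond_values[cat]) for cat in CATEGORIES
        })
    try:
        time_h = clean(row.get("time_h"))
        yield_pct = clean(row.get("yield_pct"))
        return ReactionRecord.from_smiles(
            row["reaction"],
            conditions=conditions,
            time_h=float(time_h) if time_h is not None else None,
            yield_pct=float(yield_pct) if yield_pct is not None else None,
            reference=clean(row.get("reference")),
            validate=validate,
        )
    except (ChemistryParseError, ReactionFormatError, ValueError, KeyError) as exc:
        raise DatasetFormatError(f"line {lineno}: {exc}") from exc


def write_dataset(
    records: Sequence[ReactionRecord], path: str | Path, format: str = "jsonl"
) -> None:
    """Write records as JSON-lines or TSV with the standard column set."""
    path = Path(path)
    if format == "jsonl":
        with path.open("w") as fh:
            for rec in records:
                fh.write(json.dumps(_record_to_row(rec)) + "\n")
    elif format == "delimited":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_FIELDS, delimiter="\t")
            writer.writeheader()
            for rec in records:
                row = _record_to_row(rec)
                writer.writerow({k: ("" if row[k] is None else row[k]) for k in _FIELDS})
    else:
        raise ValueError(f"unknown dataset format {format!r} (jsonl|delimited)")


def read_dataset(
    path: str | Path, format: str = "jsonl", validate: bool = True
) -> list[ReactionRecord]:
    """Read records, validating every SMILES; errors carry line numbers."""
    path = Path(path)
    records: list[ReactionRecord] = []
    if format == "jsonl":
        with path.open() as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise DatasetFormatError(f"line {lineno}: bad JSON: {exc}") from exc
                records.append(_row_to_record(row, lineno, validate))
    elif format == "delimited":
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for lineno, row in enumerate(reader, start=2):
                records.append(_row_to_record(row, lineno, validate))
    else:
        raise ValueError(f"unknown dataset format {format!r} (jsonl|delimited)")
    return records


# ---------------------------------------------------------------------------
# synonym dictionary asset
# ---------------------------------------------------------------------------


def load_synonyms(path: str | Path) -> dict[str, str]:
    """Load a tab-separated ``raw<TAB>canonical`` synonym dictionary."""
    table: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            raw, canon = line.split("\t")
            table[raw] = canon
    return table


def default_synonyms() -> dict[str, str]:
    """The synonym dictionary shipped with the package."""
    return load_synonyms(Path(__file__).parent / "data" / "synonyms.tsv")
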