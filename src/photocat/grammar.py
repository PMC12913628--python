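"""Synthetic condition-dependent reaction grammar.

Generates valid multi-reactant reaction datasets whose product outcomes depend
on the reaction conditions, emulating the statistical structure of a curated
photocatalysis database without any download. Molecules are assembled by
concatenating attachable SMILES fragments (every fragment is valid alone,
starts and ends on an attachable carbon, and concatenation of fragments is
again valid SMILES).

Four reaction templates are used:

``branch``    R1-C(=O)O + R2-Br  ->  R1-CORE-R2[-O]
              CORE is ``C(=O)`` (ketone) when no acid is present in the
              *base-or-acid* slot and ``C=C`` (alkene) when an acid (TfOH,
              TFA) is present — the same reactants give different main
              products under different conditions, mirroring how a strong
              acid can redirect a photocatalytic reaction from a carbonyl to
              an alkene product. An "oxidative" photocatalyst additionally
              appends a terminal ``O``.
``ester``     R1-C(=O)O + R2-O   ->  R1-C(=O)O-R2          (condition-free)
``amine``     R1-N + R2-Br       ->  R1-N-R2               (condition-free)
``threecomp`` R1-C(=O)O + R2-Br + R3-N -> R1-C(=O)N(R3)R2  (condition-free,
              three-component)

Only the photocatalyst (terminal ``O`` or not) and the base-or-acid slot
(ketone vs alkene core) influence outcomes; additive, wavelength and solvent
are drawn independently at random and are deliberately uninformative, so that
condition-ablation curves rise exactly on the informative categories.

``ambiguity_fraction`` is the fraction of *records* that belong to
condition-ambiguous pairs: two records with identical reactants and identical
photocatalyst group whose base-or-acid slots fall on opposite sides of the
acid branch, hence distinct products. A condition-blind predictor can resolve
at most half of those records, giving the accuracy ceiling
``1 - ambiguity_fraction / 2``.

Reactant-set instantiations are sampled without replacement, and a
deterministic hash partition of the instantiation space provides disjoint
train/test splits (held-out records use *unseen* reactant combinations of
seen templates).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .records import (
    CATEGORIES,
    ConditionNames,
    ConditionVocabulary,
    Molecule,
    ReactionRecord,
    canonicalize,
)
from .tokenization import AugmentationParams, SourceTarget, span_mask, tokenize_smiles

__all__ = [
    "GrammarSpec",
    "SyntheticDataset",
    "NoTemplateError",
    "sample_molecule",
    "apply_grammar",
    "generate_dataset",
    "generate_train_test",
    "generate_pretrain_corpus",
    "denoising_pairs",
    "grammar_vocabulary",
    "default_spec",
]


class NoTemplateError(ValueError):
    """The given reactants match none of the grammar's templates."""


_ACID_MARKER = "C(=O)O"
_KETONE_CORE = "C(=O)"
_ALKENE_CORE = "C=C"

TEMPLATES = ("branch", "ester", "amine", "threecomp")


@dataclass(frozen=True)
class GrammarSpec:
    """Parameters of the synthetic reaction grammar."""

    fragments: tuple[str, ...] = (
        "C",
        "CC",
        "CCC",
        "COC",
        "COCC",
        "CC(C)",
        "CC=CC",
        "CC(F)(F)C",
        "CCSC",
        "c1ccccc1",
        "c1ccncc1",
        "c1ccoc1",
    )
    #: superset alphabet for the condition-free pretraining corpus
    extra_pretrain_fragments: tuple[str, ...] = (
        "CCCC",
        "CC#CC",
        "CCOCC",
        "Cc1ccccc1",
    )
    fragments_per_molecule: tuple[int, int] = (1, 2)
    #: cap on assembled substituent length (characters); keeps sequences short
    max_r_length: int = 9
    ambiguity_fraction: float = 0.5
    #: sampling weights of the four templates for non-paired records
    singleton_weights: tuple[float, ...] = (0.25, 0.2, 0.2, 0.35)

    photocatalysts: tuple[str, ...] = (
        "Ru(bpy)3Cl2",
        "Eosin Y",
        "Acr+-Mes",
        "Ir(ppy)3",
        "4CzIPN",
        "autocatalysis",
    )
    oxidative_photocatalysts: frozenset[str] = frozenset(
        {"Ru(bpy)3Cl2", "Eosin Y", "Acr+-Mes"}
    )
    non_acids: tuple[str | None, ...] = (None, "K2CO3", "Cs2CO3")
    acids: tuple[str, ...] = ("TfOH", "TFA")
    additives: tuple[str | None, ...] = (None, "LiBr", "TBAB", "PPh3")
    wavelengths: tuple[str, ...] = ("390 nm", "427 nm", "blue LED", "white LED")
    solvents: tuple[str, ...] = ("MeCN", "DMSO", "DCM", "DMF")

    #: condition categories that actually influence product outcomes
    n_conditions_active: tuple[str, ...] = ("photocatalyst", "base_or_acid")

    def __post_init__(self) -> None:
        if not self.fragments:
            raise ValueError("fragment alphabet must be non-empty")
        if not 0.0 <= self.ambiguity_fraction <= 1.0:
            raise ValueError("ambiguity_fraction must be in [0, 1]")
        lo, hi = self.fragments_per_molecule
        if lo < 1 or hi < lo:
            raise ValueError("fragments_per_molecule must be an ordered pair >= 1")

    def is_acid(self, base_or_acid: str | None) -> bool:
        return base_or_acid in self.acids

    def is_oxidative(self, photocatalyst: str | None) -> bool:
        return photocatalyst in self.oxidative_photocatalysts

    def r_strings(self, pretrain: bool = False) -> tuple[str, ...]:
        """All distinct substituent strings (1..max fragments, sorted)."""
        frags = self.fragments + (self.extra_pretrain_fragments if pretrain else ())
        lo, hi = self.fragments_per_molecule
        out: set[str] = set()
        for k in range(lo, hi + 1):
            for combo in itertools.product(frags, repeat=k):
                s = "".join(combo)
                if len(s) <= self.max_r_length:
                    out.add(s)
        return tuple(sorted(out))


def default_spec() -> GrammarSpec:
    return GrammarSpec()


def grammar_vocabulary(spec: GrammarSpec) -> ConditionVocabulary:
    """The fixed condition vocabulary covering every name the grammar emits."""
    vocab = ConditionVocabulary()
    for name in spec.photocatalysts:
        vocab.add("photocatalyst", name)
    for name in (*spec.non_acids, *spec.acids):
        if name is not None:
            vocab.add("base_or_acid", name)
    for name in spec.additives:
        if name is not None:
            vocab.add("additive", name)
    for name in spec.wavelengths:
        vocab.add("wavelength", name)
    for name in spec.solvents:
        vocab.add("solvent", name)
    return vocab


# ---------------------------------------------------------------------------
# molecule and product assembly
# ---------------------------------------------------------------------------


def sample_molecule(spec: GrammarSpec, rng: np.random.Generator) -> Molecule:
    """A random valid molecule assembled from the fragment alphabet."""
    if not spec.fragments:
        raise ValueError("fragment alphabet must be non-empty")
    lo, hi = spec.fragments_per_molecule
    k = int(rng.integers(lo, hi + 1))
    parts = [spec.fragments[int(i)] for i in rng.integers(0, len(spec.fragments), k)]
    smiles = "".join(parts)
    canonicalize(smiles)  # every assembled string must be valid
    return Molecule(smiles)


def _reactants_for(template: str, rs: Sequence[str]) -> tuple[str, ...]:
    if template == "branch":
        return (rs[0] + _ACID_MARKER, rs[1] + "Br")
    if template == "ester":
        return (rs[0] + _ACID_MARKER, rs[1] + "O")
    if template == "amine":
        return (rs[0] + "N", rs[1] + "Br")
    if template == "threecomp":
        return (rs[0] + _ACID_MARKER, rs[1] + "Br", rs[2] + "N")
    raise ValueError(f"unknown template {template!r}")


def _arity(template: str) -> int:
    return 3 if template == "threecomp" else 2


def _product_for(
    template: str, rs: Sequence[str], conditions: ConditionNames | None, spec: GrammarSpec
) -> str:
    if template == "branch":
        if conditions is None:
            raise NoTemplateError("branch template requires conditions")
        core = _ALKENE_CORE if spec.is_acid(conditions.base_or_acid) else _KETONE_CORE
        suffix = "O" if spec.is_oxidative(conditions.photocatalyst) else ""
        return rs[0] + core + rs[1] + suffix
    if template == "ester":
        return rs[0] + _ACID_MARKER + rs[1]
    if template == "amine":
        return rs[0] + "N" + rs[1]
    if template == "threecomp":
        # N-substituents written in reactant order (same amide either way)
        return rs[0] + "C(=O)N(" + rs[1] + ")" + rs[2]
    raise ValueError(f"unknown template {template!r}")


def _match_template(reactants: Sequence[str]) -> tuple[str, list[str]]:
    """Identify the template of grammar-rendered reactant strings.

    Operates on the strings exactly as the grammar renders them (the
    functional-group marker is a literal suffix); canonical re-renderings are
    not recognized — ground-truth lookups on canonical forms go through
    :class:`SyntheticDataset` instead.
    """
    if len(reactants) == 3:
        r1, r2, r3 = reactants
        if r1.endswith(_ACID_MARKER) and r2.endswith("Br") and r3.endswith("N"):
            return "threecomp", [r1[: -len(_ACID_MARKER)], r2[:-2], r3[:-1]]
    elif len(reactants) == 2:
        r1, r2 = reactants
        if r1.endswith(_ACID_MARKER) and r2.endswith("Br"):
            return "branch", [r1[: -len(_ACID_MARKER)], r2[:-2]]
        if r1.endswith(_ACID_MARKER) and r2.endswith("O"):
            return "ester", [r1[: -len(_ACID_MARKER)], r2[:-1]]
        if r1.endswith("N") and r2.endswith("Br"):
            return "amine", [r1[:-1], r2[:-2]]
    raise NoTemplateError(f"no template matches reactants {list(reactants)!r}")


def apply_grammar(
    reactants: Sequence[str],
    conditions: ConditionNames | None,
    spec: GrammarSpec,
) -> Molecule:
    """Deterministic product of grammar-rendered reactants under conditions."""
    template, rs = _match_template(reactants)
    raw = _product_for(template, rs, conditions, spec)
    return canonicalize(raw)


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _mix64(x: int) -> int:
    """splitmix64 finalizer — a stable integer hash for split assignment."""
    x = (x + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return x ^ (x >> 31)


def _key_hash(template: str, idxs: tuple[int, ...], salt: int) -> float:
    h = salt
    for v in (TEMPLATES.index(template), *idxs):
        h = _mix64(h ^ (v + 0x632BE59BD9B4E019))
    return h / 2**64


@dataclass
class SyntheticDataset:
    """Generated records plus the ground-truth (reactants, conditions) -> product map."""

    records: list[ReactionRecord]
    spec: GrammarSpec
    #: (sorted canonical reactants, branch signature) -> canonical product
    ground_truth: dict[tuple, str] = field(default_factory=dict)

    def branch_signature(self, conditions: ConditionNames | None) -> tuple | None:
        if conditions is None:
            return None
        return (
            self.spec.is_oxidative(conditions.photocatalyst),
            self.spec.is_acid(conditions.base_or_acid),
        )

    def truth_key(
        self, reactant_smiles: Iterable[str], conditions: ConditionNames | None
    ) -> tuple:
        reactants = tuple(sorted(canonicalize(s).smiles for s in reactant_smiles))
        return (reactants, self.branch_signature(conditions))

    def product_for(
        self, reactant_smiles: Iterable[str], conditions: ConditionNames | None
    ) -> str | None:
        """Canonical ground-truth product, or None if never generated."""
        key = self.truth_key(reactant_smiles, conditions)
        hit = self.ground_truth.get(key)
        if hit is None:
            # condition-free templates were stored with a None signature
            hit = self.ground_truth.get((key[0], None))
        return hit

    def vocabulary(self) -> ConditionVocabulary:
        return grammar_vocabulary(self.spec)


def _sample_conditions(spec: GrammarSpec, rng: np.random.Generator) -> ConditionNames:
    def pick(options: Sequence):
        return options[int(rng.integers(0, len(options)))]

    return ConditionNames(
        photocatalyst=pick(spec.photocatalysts),
        base_or_acid=pick((*spec.non_acids, *spec.acids)),
        additive=pick(spec.additives),
        wavelength=pick(spec.wavelengths),
        solvent=pick(spec.solvents),
    )


def _make_record(
    template: str,
    rs: Sequence[str],
    conditions: ConditionNames,
    spec: GrammarSpec,
    rng: np.random.Generator,
    index: int,
) -> tuple[ReactionRecord, str]:
    reactants = _reactants_for(template, rs)
    # products are stored as the grammar renders them (the way literature
    # databases store author-written SMILES); metrics canonicalize anyway
    product = _product_for(template, rs, conditions, spec)
    rec = ReactionRecord(
        reactants=tuple(Molecule(r) for r in reactants),
        products=(Molecule(product),),
        conditions=conditions,
        time_h=round(float(rng.uniform(0.5, 48.0)), 1),
        yield_pct=round(float(rng.uniform(15.0, 99.0)), 1),
        reference=f"synthetic-{index:06d}",
    )
    return rec, canonicalize(product).smiles


def _sample_key(
    template: str,
    n_r: int,
    rng: np.random.Generator,
    used: set,
    keep,
    max_tries: int = 10_000,
) -> tuple[int, ...]:
    arity = _arity(template)
    for _ in range(max_tries):
        idxs = tuple(int(i) for i in rng.integers(0, n_r, arity))
        key = (template, idxs)
        if key in used or not keep(template, idxs):
            continue
        used.add(key)
        return idxs
    raise RuntimeError(
        "could not sample a fresh template instantiation; "
        "reactant space too small for the requested dataset size"
    )


def generate_dataset(
    spec: GrammarSpec,
    n: int,
    seed: int,
    keep=None,
) -> SyntheticDataset:
    """Generate ``n`` condition-annotated records.

    ``keep(template, idxs) -> bool`` optionally restricts the instantiation
    space (used for disjoint train/test splits). Reactant-set instantiations
    are sampled without replacement, so with ``ambiguity_fraction = 0`` no
    reactant set ever appears with two different products.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    keep = keep or (lambda t, i: True)
    r_all = spec.r_strings()
    n_r = len(r_all)
    used: set = set()

    n_pairs = int(round(spec.ambiguity_fraction * n / 2.0))
    n_single = n - 2 * n_pairs

    entries: list[tuple[str, tuple[int, ...], ConditionNames]] = []

    for _ in range(n_pairs):
        idxs = _sample_key("branch", n_r, rng, used, keep)
        shared = _sample_conditions(spec, rng)
        no_acid = spec.non_acids[int(rng.integers(0, len(spec.non_acids)))]
        acid = spec.acids[int(rng.integers(0, len(spec.acids)))]
        for base in (no_acid, acid):
            entries.append((
                "branch",
                idxs,
                ConditionNames(
                    photocatalyst=shared.photocatalyst,
                    base_or_acid=base,
                    additive=shared.additive,
                    wavelength=shared.wavelength,
                    solvent=shared.solvent,
                ),
            ))

    weights = np.asarray(spec.singleton_weights, dtype=float)
    weights = weights / weights.sum()
    for _ in range(n_single):
        template = TEMPLATES[int(rng.choice(len(TEMPLATES), p=weights))]
        idxs = _sample_key(template, n_r, rng, used, keep)
        entries.append((template, idxs, _sample_conditions(spec, rng)))

    order = rng.permutation(len(entries))
    records: list[ReactionRecord] = []
    ds = SyntheticDataset(records=records, spec=spec)
    for out_i, ent_i in enumerate(order):
        template, idxs, conditions = entries[int(ent_i)]
        rs = [r_all[i] for i in idxs]
        rec, product = _make_record(template, rs, conditions, spec, rng, out_i)
        key = ds.truth_key(
            [m.smiles for m in rec.reactants],
            conditions if template == "branch" else None,
        )
        prev = ds.ground_truth.setdefault(key, product)
        if prev != product:  # the map must stay a function
            raise RuntimeError("grammar produced conflicting products for one key")
        records.append(rec)
    return ds


def generate_train_test(
    spec: GrammarSpec,
    n_train: int,
    n_test: int,
    seed: int,
    test_fraction: float = 0.2,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Datasets over disjoint reactant-set instantiations of the same templates.

    Every template instantiation (template, substituent indices) is assigned
    to the train or test side by a deterministic hash, so held-out records use
    reactant combinations never seen in training.
    """
    salt = _mix64(seed)

    def in_test(t, i):
        return _key_hash(t, i, salt) < test_fraction

    train = generate_dataset(spec, n_train, seed, keep=lambda t, i: not in_test(t, i))
    test = generate_dataset(spec, n_test, seed + 1, keep=in_test)
    return train, test


def generate_pretrain_corpus(
    spec: GrammarSpec, n: int, seed: int
) -> SyntheticDataset:
    """Condition-free reaction corpus over a superset fragment alphabet.

    Emulates a large generic pretraining set: only the condition-independent
    templates appear (never the condition-branched one), drawn over the
    fine-tune alphabet extended with extra fragments, so pretraining overlaps
    the fine-tune distribution without revealing condition-dependent products.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    r_all = spec.r_strings(pretrain=True)
    n_r = len(r_all)
    templates = ("ester", "amine", "threecomp")
    records: list[ReactionRecord] = []
    ds = SyntheticDataset(records=records, spec=spec)
    for i in range(n):
        template = templates[int(rng.integers(0, len(templates)))]
        idxs = tuple(int(j) for j in rng.integers(0, n_r, _arity(template)))
        rs = [r_all[j] for j in idxs]
        reactants = _reactants_for(template, rs)
        product = _product_for(template, rs, None, spec)
        records.append(
            ReactionRecord(
                reactants=tuple(Molecule(r) for r in reactants),
                products=(Molecule(product),),
                conditions=None,
                reference=f"pretrain-{i:06d}",
            )
        )
        ds.ground_truth.setdefault(
            ds.truth_key(reactants, None), canonicalize(product).smiles
        )
    return ds


def denoising_pairs(
    spec: GrammarSpec,
    n: int,
    seed: int,
    params: AugmentationParams | None = None,
) -> list[SourceTarget]:
    """Molecule-level span-mask denoising pairs (masked molecule -> molecule).

    The first stage of the staged transfer recipe: random molecules from the
    pretrain alphabet with contiguous token spans replaced by the mask token.
    """
    params = params or AugmentationParams(apply_probability=1.0)
    rng = np.random.default_rng(seed)
    big = GrammarSpec(
        fragments=spec.fragments + spec.extra_pretrain_fragments,
        fragments_per_molecule=spec.fragments_per_molecule,
    )
    pairs = []
    for _ in range(n):
        mol = sample_molecule(big, rng)
        toks = tokenize_smiles(mol.smiles)
        masked = span_mask(toks, rng, params)
        pairs.append(SourceTarget(tuple(masked), tuple(toks), "denoise"))
    return pairs
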