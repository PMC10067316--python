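"""Chemical value objects: molecules, chemical equations, fingerprints.

The identity layer of the toolkit lives here.  A :class:`Molecule` is a value
object whose identity (``uid``) is a structure-derived string computed under a
configurable :class:`IdentityPolicy`; a :class:`ChemicalEquation` is a value
object whose identity is derived from its reactant and product molecules
*only* — reagents, conditions and procedures are deliberately outside the
identity layer, so two writings of the same transformation with different
catalysts map onto the same node.

RDKit does the actual chemistry: parsing, canonicalization, InChIKey
generation, Morgan and reaction-difference fingerprints.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from rdkit import Chem, DataStructs, RDLogger
from rdkit.Chem import rdChemReactions, rdFingerprintGenerator
from rdkit.Chem.inchi import MolToInchiKey

from .exceptions import (
    InvalidStructureError,
    MalformedReactionError,
    TypeMismatchError,
)

# RDKit is chatty on stderr for every failed parse attempt; errors are
# re-raised as InvalidStructureError with the offending string instead.
RDLogger.DisableLog("rdApp.*")

MOLECULE = "molecule"
CHEMICAL_EQUATION = "chemical_equation"

REACTANT = "reactant"
REAGENT = "reagent"
PRODUCT = "product"

#: Registered uid policies.  The default keeps stereochemistry; the no-stereo
#: variant collapses stereoisomers onto one node; the InChIKey variant
#: additionally collapses most tautomer pairs.
CANONICAL_ISOMERIC_SMILES = "canonical-isomeric-smiles"
CANONICAL_SMILES_NO_STEREO = "canonical-smiles-no-stereo"
INCHIKEY = "inchikey"

_POLICIES = (CANONICAL_ISOMERIC_SMILES, CANONICAL_SMILES_NO_STEREO, INCHIKEY)


@dataclass(frozen=True)
class IdentityPolicy:
    """Which structure-derived string defines molecular identity."""

    policy_name: str = CANONICAL_ISOMERIC_SMILES

    def __post_init__(self) -> None:
        if self.policy_name not in _POLICIES:
            raise ValueError(
                f"unknown identity policy {self.policy_name!r}; "
                f"choose one of {_POLICIES}"
            )


DEFAULT_POLICY = IdentityPolicy()


@dataclass(frozen=True)
class FingerprintParams:
    """Fingerprint and similarity configuration.

    Defaults follow the common route-comparison setup: Morgan (circular)
    fingerprints of radius 2 folded to 2048 bits for molecules, difference
    fingerprints for reactions, Tanimoto similarity for both.
    """

    molecular_fp_type: str = "morgan"
    morgan_radius: int = 2
    n_bits: int = 2048
    reaction_fp_type: str = "difference"  # or "structural"
    similarity_metric: str = "tanimoto"  # or "dice"

    def __post_init__(self) -> None:
        if self.molecular_fp_type != "morgan":
            raise ValueError(f"unknown molecular fp {self.molecular_fp_type!r}")
        if self.reaction_fp_type not in ("difference", "structural"):
            raise ValueError(f"unknown reaction fp {self.reaction_fp_type!r}")
        if self.similarity_metric not in ("tanimoto", "dice"):
            raise ValueError(f"unknown metric {self.similarity_metric!r}")


DEFAULT_FP_PARAMS = FingerprintParams()


class Molecule:
    """A chemical compound as a value object.

    Equality and hashing are defined on ``uid`` alone, so instances built
    from different writings of the same structure compare equal.
    """

    kind = MOLECULE

    __slots__ = ("input_string", "canonical_form", "uid", "policy", "_fp_cache")

    def __init__(self, input_string: str, canonical_form: str, uid: str,
                 policy: IdentityPolicy) -> None:
        self.input_string = input_string
        self.canonical_form = canonical_form
        self.uid = uid
        self.policy = policy
        self._fp_cache: dict = {}

    # value-object semantics ------------------------------------------------
    def __eq__(self, other: object) -> bool:
        return isinstance(other, Molecule) and other.uid == self.uid

    def __hash__(self) -> int:
        return hash((self.kind, self.uid))

    def __repr__(self) -> str:
        return f"Molecule({self.canonical_form!r})"

    # chemistry --------------------------------------------------------------
    def to_mol(self) -> Chem.Mol:
        return Chem.MolFromSmiles(self.canonical_form)

    def fingerprint(self, params: FingerprintParams = DEFAULT_FP_PARAMS):
        key = (params.molecular_fp_type, params.morgan_radius, params.n_bits)
        fp = self._fp_cache.get(key)
        if fp is None:
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=params.morgan_radius, fpSize=params.n_bits
            )
            fp = gen.GetFingerprint(self.to_mol())
            self._fp_cache[key] = fp
        return fp

    # pickling (fp caches hold rdkit vectors; cheap to rebuild) -------------
    def __getstate__(self):
        return (self.input_string, self.canonical_form, self.uid, self.policy)

    def __setstate__(self, state):
        self.input_string, self.canonical_form, self.uid, self.policy = state
        self._fp_cache = {}


def canonicalize_molecule(
    input_string: str, policy: IdentityPolicy = DEFAULT_POLICY
) -> Molecule:
    """Parse a SMILES string and return its canonical :class:`Molecule`.

    Idempotent: canonicalizing ``m.canonical_form`` reproduces ``m``.

    Raises
    ------
    InvalidStructureError
        If the string does not parse, naming the offending string.
    """
    mol = Chem.MolFromSmiles(input_string)
    if mol is None:
        raise InvalidStructureError(
            f"cannot parse molecular structure: {input_string!r}"
        )
    canonical = Chem.MolToSmiles(mol)  # canonical isomeric SMILES
    if policy.policy_name == CANONICAL_ISOMERIC_SMILES:
        uid = canonical
    elif policy.policy_name == CANONICAL_SMILES_NO_STEREO:
        uid = Chem.MolToSmiles(mol, isomericSmiles=False)
    else:  # INCHIKEY
        uid = MolToInchiKey(mol)
    return Molecule(input_string, canonical, uid, policy)


class ChemicalEquation:
    """A chemical reaction as a value object.

    ``role_map`` maps each role (reactant / reagent / product) to the sorted
    tuple of molecule uids holding that role; ``molecules`` catalogs the
    unique :class:`Molecule` instances involved.  The ``uid`` hashes the
    reactant and product uids only, so reagent changes never split nodes.
    Duplicate molecules within a role are recorded in ``stoichiometry`` but
    excluded from the identity.
    """

    kind = CHEMICAL_EQUATION

    __slots__ = ("role_map", "molecules", "stoichiometry", "uid", "smiles",
                 "input_string", "policy", "_fp_cache")

    def __init__(self, role_map, molecules, stoichiometry, uid, smiles,
                 input_string, policy) -> None:
        self.role_map = role_map
        self.molecules = molecules
        self.stoichiometry = stoichiometry
        self.uid = uid
        self.smiles = smiles
        self.input_string = input_string
        self.policy = policy
        self._fp_cache: dict = {}

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ChemicalEquation) and other.uid == self.uid

    def __hash__(self) -> int:
        return hash((self.kind, self.uid))

    def __repr__(self) -> str:
        return f"ChemicalEquation({self.smiles!r})"

    @property
    def reactants(self) -> tuple:
        return self.role_map[REACTANT]

    @property
    def reagents(self) -> tuple:
        return self.role_map[REAGENT]

    @property
    def products(self) -> tuple:
        return self.role_map[PRODUCT]

    def identity_smiles(self) -> str:
        """Reagent-free ``reactants>>products`` string over canonical forms."""
        r = sorted(self.molecules[u].canonical_form for u in self.reactants)
        p = sorted(self.molecules[u].canonical_form for u in self.products)
        return f"{'.'.join(r)}>>{'.'.join(p)}"

    def fingerprint(self, params: FingerprintParams = DEFAULT_FP_PARAMS):
        key = (params.reaction_fp_type,)
        fp = self._fp_cache.get(key)
        if fp is None:
            rxn = rdChemReactions.ReactionFromSmarts(
                self.identity_smiles(), useSmiles=True
            )
            if params.reaction_fp_type == "difference":
                fp = rdChemReactions.CreateDifferenceFingerprintForReaction(rxn)
            else:
                fp = rdChemReactions.CreateStructuralFingerprintForReaction(rxn)
            self._fp_cache[key] = fp
        return fp

    def __getstate__(self):
        return (self.role_map, self.molecules, self.stoichiometry, self.uid,
                self.smiles, self.input_string, self.policy)

    def __setstate__(self, state):
        (self.role_map, self.molecules, self.stoichiometry, self.uid,
         self.smiles, self.input_string, self.policy) = state
        self._fp_cache = {}


def _equation_uid(reactant_uids, product_uids) -> str:
    """Hash of ``sorted(reactant uids) >> sorted(product uids)``."""
    payload = f"{'.'.join(sorted(reactant_uids))}>>{'.'.join(sorted(product_uids))}"
    return "CE" + hashlib.sha256(payload.encode("utf-8")).hexdigest()[:32]


def build_chemical_equation(
    reaction_string: str, policy: IdentityPolicy = DEFAULT_POLICY
) -> ChemicalEquation:
    """Build a :class:`ChemicalEquation` from reaction SMILES.

    Accepts the standard ``reactants>agents>products`` dialect (``>>`` when
    no agent block).  Role attribution: every agent-block molecule becomes a
    reagent; additionally, any molecule whose uid appears among both
    reactants and products is reassigned to reagent (it is unchanged by the
    transformation, i.e. a spectator at this identity layer).

    Raises
    ------
    MalformedReactionError
        If the text has no ``>``-separated blocks, or no reactant or no
        product remains after role attribution.
    InvalidStructureError
        Propagated from any unparsable component structure.
    """
    blocks = reaction_string.split(">")
    if len(blocks) != 3:
        raise MalformedReactionError(
            f"expected 'reactants>agents>products': {reaction_string!r}"
        )

    def parse_block(block: str) -> list[Molecule]:
        return [
            canonicalize_molecule(s, policy)
            for s in block.split(".") if s.strip()
        ]

    reactants = parse_block(blocks[0])
    agents = parse_block(blocks[1])
    products = parse_block(blocks[2])

    # spectator detection: same uid on both sides -> reagent
    reactant_uids = {m.uid for m in reactants}
    product_uids = {m.uid for m in products}
    spectators = reactant_uids & product_uids
    reagents = agents + [m for m in reactants if m.uid in spectators]
    reactants = [m for m in reactants if m.uid not in spectators]
    products = [m for m in products if m.uid not in spectators]

    if not reactants or not products:
        raise MalformedReactionError(
            f"no reactant or no product left after role attribution: "
            f"{reaction_string!r}"
        )

    molecules: dict[str, Molecule] = {}
    stoichiometry: dict[str, dict[str, int]] = {}
    role_map: dict[str, tuple] = {}
    for role, mols in ((REACTANT, reactants), (REAGENT, reagents),
                       (PRODUCT, products)):
        counts: dict[str, int] = {}
        for m in mols:
            molecules.setdefault(m.uid, m)
            counts[m.uid] = counts.get(m.uid, 0) + 1
        role_map[role] = tuple(sorted(counts))
        stoichiometry[role] = counts

    uid = _equation_uid(role_map[REACTANT], role_map[PRODUCT])

    # canonical writing with reagents preserved (outside identity)
    smiles = ">".join(
        ".".join(sorted(molecules[u].canonical_form for u in role_map[role]))
        for role in (REACTANT, REAGENT, PRODUCT)
    )
    return ChemicalEquation(role_map, molecules, stoichiometry, uid, smiles,
                            reaction_string, policy)


def _similarity(fp_a, fp_b, metric: str) -> float:
    if metric == "tanimoto":
        value = DataStructs.TanimotoSimilarity(fp_a, fp_b)
    else:
        value = DataStructs.DiceSimilarity(fp_a, fp_b)
    return min(1.0, max(0.0, value))


def chemical_similarity(
    a, b, params: FingerprintParams = DEFAULT_FP_PARAMS
) -> float:
    """Fingerprint similarity between two same-kind chemical value objects.

    Symmetric, bounded in [0, 1], exactly 1 for uid-equal inputs.

    Raises
    ------
    TypeMismatchError
        If ``a`` and ``b`` are not both Molecules or both ChemicalEquations.
    """
    if not isinstance(a, (Molecule, ChemicalEquation)) or \
            not isinstance(b, (Molecule, ChemicalEquation)):
        raise TypeMismatchError(
            f"expected Molecule or ChemicalEquation, got {type(a).__name__} "
            f"and {type(b).__name__}"
        )
    if a.kind != b.kind:
        raise TypeMismatchError(
            f"cannot compare a {a.kind} with a {b.kind}"
        )
    if a.uid == b.uid:
        return 1.0
    return _similarity(a.fingerprint(params), b.fingerprint(params),
                       params.similarity_metric)
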