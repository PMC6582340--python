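"""Similarity index chi between the search and recognition binding modes.

A DNA-binding protein recognizes its site through a set of residues that
hydrogen-bond to DNA bases (the recognition, R, patch) and slides along
DNA on its largest positively charged surface patch (the search, S,
patch).  The *similarity index* quantifies the overlap between the two:
for every specific-contact residue i,

    chi_i = sum_j q_j exp(-a r_ij / r_c) / sum_j exp(-a r_ij / r_c)

where j runs over the protein residues closer than the cutoff r_c = 8 A,
q_j in {-1, 0, +1} is the residue point charge, and a = 5 sets the decay.
chi_i is a charge-weighted neighborhood average in [-1, +1]; the protein
level chi is the arithmetic mean of chi_i over the specific-contact set.
High chi means the recognition residues sit inside the positive (search)
patch — low frustration; low or negative chi means the two patches are
disjoint — high frustration.

Charge-altering point mutations shift chi without any structural change,
which is how the effect of mutations on association kinetics is scored
(:func:`mutation_effect`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

from .errors import (
    InvalidParameterError,
    MutationError,
    NoSpecificContactsError,
    UndefinedSimilarityError,
)
from .kinetics import ModelParameters, d1d_from_si, roughness_from_experimental_d1d
from .structure import (
    CHARGE_SCHEMES,
    Residue,
    ResidueId,
    StructureModel,
    assign_charges,
)

__all__ = [
    "SpecificContactSet", "ResidueSimilarity", "SimilarityResult",
    "CONTACT_RULES", "detect_specific_contacts", "residue_similarity",
    "protein_similarity", "apply_mutation", "mutation_effect",
    "chi_sigma_correlation",
]

#: contact rule name -> (default cutoff in Angstrom, description)
CONTACT_RULES = {
    "base-polar": (3.5, "protein N/O atom within cutoff of a DNA-base N/O "
                        "atom (hydrogen-bond geometry, no angle term)"),
    "base-heavy": (4.5, "any protein heavy atom within cutoff of any "
                        "DNA-base heavy atom"),
}

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}


@dataclass(frozen=True)
class SpecificContactSet:
    """Protein residues in specific (recognition-mode) contact with DNA."""

    ids: tuple[ResidueId, ...]
    rule: str
    cutoff: float

    def __contains__(self, rid: ResidueId) -> bool:
        return rid in self.ids

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ResidueSimilarity:
    residue_name: str
    chi_i: float
    n_neighbors: int


@dataclass(frozen=True)
class SimilarityResult:
    """Per-residue chi_i over the specific-contact set and the protein chi.

    Carries full provenance: decay constant ``a``, cutoff ``r_c`` (A),
    charge scheme, contact rule/cutoff, distance convention, whether the
    residue itself entered its own weighted average, and any contact
    residues excluded because chi_i was undefined.
    """

    per_residue: dict[ResidueId, ResidueSimilarity]
    chi: float
    a: float
    r_c: float
    charge_scheme: str
    contact_rule: str
    contact_cutoff: float
    distance_convention: str
    include_self: bool
    excluded: tuple[ResidueId, ...] = ()

    def as_dict(self) -> dict:
        return {
            "chi": self.chi,
            "n_contacts": len(self.per_residue),
            "per_residue": {
                f"{rid.chain}:{rid.seq_number}{rid.insertion_code}": {
                    "residue_name": e.residue_name, "chi_i": e.chi_i,
                    "n_neighbors": e.n_neighbors,
                } for rid, e in sorted(self.per_residue.items())},
            "parameters": {
                "a": self.a, "r_c_angstrom": self.r_c,
                "charge_scheme": self.charge_scheme,
                "contact_rule": self.contact_rule,
                "contact_cutoff_angstrom": self.contact_cutoff,
                "distance_convention": self.distance_convention,
                "include_self": self.include_self,
            },
        }


def _polar_coords(res: Residue) -> np.ndarray:
    pts = [[a.x, a.y, a.z] for a in res.atoms if a.element in ("N", "O")]
    return np.array(pts) if pts else np.empty((0, 3))


def _base_coords(res: Residue, polar_only: bool) -> np.ndarray:
    atoms = res.base_atoms()
    if polar_only:
        atoms = tuple(a for a in atoms if a.element in ("N", "O"))
    return (np.array([[a.x, a.y, a.z] for a in atoms])
            if atoms else np.empty((0, 3)))


def detect_specific_contacts(s: StructureModel, rule: str = "base-polar",
                             cutoff: float | None = None
                             ) -> SpecificContactSet:
    """Find the protein residues in specific contact with DNA bases.

    ``base-polar`` (default, cutoff 3.5 A): an N or O atom of the residue
    lies within the cutoff of an N/O atom of a DNA *base* (backbone
    phosphates and sugars are the non-specific interface and are
    excluded).  ``base-heavy`` (cutoff 4.5 A): any heavy-atom pair with a
    base atom.  The rule and cutoff used are recorded in the result.
    """
    if rule not in CONTACT_RULES:
        raise InvalidParameterError(
            f"unknown contact rule {rule!r}; known: {sorted(CONTACT_RULES)}")
    if cutoff is None:
        cutoff = CONTACT_RULES[rule][0]
    if cutoff <= 0:
        raise InvalidParameterError(f"cutoff must be > 0, got {cutoff!r}")
    polar_only = rule == "base-polar"
    base_pts = [_base_coords(r, polar_only) for r in s.dna_residues]
    base_pts = [p for p in base_pts if p.size]
    if not base_pts:
        raise NoSpecificContactsError(
            f"{s.source_id}: DNA residues expose no base atoms for rule "
            f"{rule!r}")
    dna = np.vstack(base_pts)
    ids = []
    for res in s.protein_residues:
        pts = _polar_coords(res) if polar_only else res.coords()
        if pts.size and cdist(pts, dna).min() <= cutoff:
            ids.append(res.rid)
    if not ids:
        raise NoSpecificContactsError(
            f"{s.source_id}: no specific contacts under rule {rule!r} at "
            f"{cutoff:g} A — non-specific complex or mis-selected chains?")
    return SpecificContactSet(ids=tuple(sorted(ids)), rule=rule,
                              cutoff=float(cutoff))


def _residue_distance(r1: Residue, r2: Residue, convention: str) -> float:
    if convention == "min-heavy":
        return float(cdist(r1.coords(), r2.coords()).min())
    if convention == "cb":
        def rep(res: Residue) -> np.ndarray:
            for name in ("CB", "CA"):  # glycine falls back to CA
                for a in res.atoms:
                    if a.name == name:
                        return a.position
            return res.coords().mean(axis=0)
        return float(np.linalg.norm(rep(r1) - rep(r2)))
    raise InvalidParameterError(
        f"unknown distance convention {convention!r}; "
        "known: ['min-heavy', 'cb']")


def residue_similarity(rid: ResidueId, s: StructureModel, a: float = 5.0,
                       r_c: float = 8.0, *, include_self: bool = True,
                       distance: str = "min-heavy") -> float:
    """chi_i of one residue: charge average over neighbors within r_c.

    Weights are ``exp(-a r_ij / r_c)`` with ``r_ij`` the inter-residue
    distance under ``distance`` ("min-heavy": minimum heavy-atom pair
    distance, the default; "cb": C-beta positions).  Neighbors j are
    protein residues strictly closer than ``r_c``; with ``include_self``
    the residue contributes its own charge at r = 0 (weight 1).
    """
    if a <= 0 or r_c <= 0:
        raise InvalidParameterError("a and r_c must be > 0")
    center = s.protein(rid)
    num = 0.0
    den = 0.0
    n_neigh = 0
    for other in s.protein_residues:
        if other.rid == rid:
            if include_self:
                num += center.charge
                den += 1.0
                n_neigh += 1
            continue
        r = _residue_distance(center, other, distance)
        if r < r_c:
            w = math.exp(-a * r / r_c)
            num += other.charge * w
            den += w
            n_neigh += 1
    if den == 0.0:
        raise UndefinedSimilarityError(
            f"chi_i undefined for {center.label()}: no neighbors within "
            f"{r_c:g} A and include_self is off")
    return num / den


def protein_similarity(s: StructureModel, contacts: SpecificContactSet,
                       a: float = 5.0, r_c: float = 8.0, *,
                       include_self: bool = True,
                       distance: str = "min-heavy") -> SimilarityResult:
    """Protein-level chi: mean of chi_i over the specific-contact set.

    Contact residues whose chi_i is undefined (no neighbors inside r_c
    with self-inclusion off) are excluded from the average with a warning
    and listed in ``result.excluded``.
    """
    if len(contacts) == 0:
        raise NoSpecificContactsError("empty specific-contact set")
    if s.charge_scheme is None:
        raise InvalidParameterError(
            "structure has no charges; call assign_charges first")
    per: dict[ResidueId, ResidueSimilarity] = {}
    excluded: list[ResidueId] = []
    for rid in contacts.ids:
        res = s.protein(rid)
        try:
            chi_i = residue_similarity(rid, s, a, r_c,
                                       include_self=include_self,
                                       distance=distance)
        except UndefinedSimilarityError as exc:
            warnings.warn(str(exc), stacklevel=2)
            excluded.append(rid)
            continue
        n_neigh = sum(
            1 for other in s.protein_residues
            if (other.rid == rid and include_self)
            or (other.rid != rid
                and _residue_distance(res, other, distance) < r_c))
        per[rid] = ResidueSimilarity(res.name, chi_i, n_neigh)
    if not per:
        raise UndefinedSimilarityError(
            "every contact residue had undefined chi_i")
    chi = float(np.mean([e.chi_i for e in per.values()]))
    return SimilarityResult(
        per_residue=per, chi=chi, a=float(a), r_c=float(r_c),
        charge_scheme=s.charge_scheme, contact_rule=contacts.rule,
        contact_cutoff=contacts.cutoff, distance_convention=distance,
        include_self=include_self, excluded=tuple(excluded))


def _parse_mutation(spec: str) -> tuple[str | None, str, int, str]:
    """'A:R198Q' or 'R198Q' -> (chain or None, wt 1-letter, pos, new)."""
    chain = None
    body = spec.strip()
    if ":" in body:
        chain, body = body.split(":", 1)
        chain = chain.strip()
    body = body.strip().upper()
    if len(body) < 3 or body[0] not in ONE_TO_THREE \
            or body[-1] not in ONE_TO_THREE or not body[1:-1].isdigit():
        raise MutationError(
            f"malformed mutation {spec!r}; expected e.g. 'A:R198Q'")
    return chain, body[0], int(body[1:-1]), body[-1]


def apply_mutation(s: StructureModel, mutations: list[str] | str,
                   scheme: str | None = None) -> StructureModel:
    """Apply point mutations as charge edits: rename the residue and
    reassign its charge under the active scheme; coordinates are left
    untouched (no side-chain rebuilding — chi consumes only charges and
    distances, so a charge-level mutation model is sufficient and keeps
    the wild-type geometry as the common frame).

    Mutation strings are ``[chain:]X<pos>Y`` with one-letter codes; the
    wild-type letter must match the structure.
    """
    if isinstance(mutations, str):
        mutations = [m for m in mutations.split(",") if m.strip()]
    scheme = scheme or s.charge_scheme or "default"
    table = CHARGE_SCHEMES[scheme]
    out = s
    for spec in mutations:
        chain, wt, pos, new = _parse_mutation(spec)
        matches = [r for r in out.protein_residues
                   if r.seq_number == pos
                   and (chain is None or r.chain == chain)]
        if not matches:
            raise MutationError(
                f"{spec!r}: no residue at position {pos}"
                + (f" in chain {chain}" if chain else ""))
        if len(matches) > 1:
            raise MutationError(
                f"{spec!r}: position {pos} is ambiguous across chains "
                f"{sorted(r.chain for r in matches)}; prefix a chain")
        res = matches[0]
        actual = THREE_TO_ONE.get(res.name)
        if actual != wt:
            raise MutationError(
                f"{spec!r}: structure has {res.name} ({actual}) at "
                f"{res.label()}, not {wt}")
        new3 = ONE_TO_THREE[new]
        mutated = Residue(chain=res.chain, seq_number=res.seq_number,
                          insertion_code=res.insertion_code, name=new3,
                          atoms=res.atoms, is_dna=False,
                          charge=table.get(new3, 0))
        out = out.replace_protein_residue(res.rid, mutated)
    return out


def mutation_effect(s: StructureModel, mutations: list[str] | str, *,
                    pin_contacts: bool = True, rule: str = "base-polar",
                    cutoff: float | None = None, a: float = 5.0,
                    r_c: float = 8.0, include_self: bool = True,
                    distance: str = "min-heavy") -> dict:
    """Change in similarity index caused by point mutations.

    With ``pin_contacts`` (default) the wild-type specific-contact set is
    reused for the mutant, so delta-chi isolates the electrostatic effect
    of the charge edit; otherwise contacts are re-detected on the mutant.

    Returns a dict with ``chi_wt``, ``chi_mut``, ``delta_chi`` and
    ``relative_change`` (= delta_chi / chi_wt) plus both full results.
    """
    if s.charge_scheme is None:
        s = assign_charges(s)
    contacts_wt = detect_specific_contacts(s, rule, cutoff)
    res_wt = protein_similarity(s, contacts_wt, a, r_c,
                                include_self=include_self, distance=distance)
    mutant = apply_mutation(s, mutations)
    contacts_mut = (contacts_wt if pin_contacts
                    else detect_specific_contacts(mutant, rule, cutoff))
    res_mut = protein_similarity(mutant, contacts_mut, a, r_c,
                                 include_self=include_self,
                                 distance=distance)
    delta = res_mut.chi - res_wt.chi
    return {
        "mutations": mutations if isinstance(mutations, list)
        else [m.strip() for m in mutations.split(",")],
        "chi_wt": res_wt.chi, "chi_mut": res_mut.chi, "delta_chi": delta,
        "relative_change": delta / res_wt.chi if res_wt.chi != 0
        else float("nan"),
        "pin_contacts": pin_contacts,
        "wild_type": res_wt, "mutant": res_mut,
    }


def chi_sigma_correlation(records, params: ModelParameters
                          ) -> tuple[float, np.ndarray]:
    """Correlate similarity indices with landscape roughness from D_1D.

    ``records`` is a sequence of ``(chi, d1d_m2_per_s)`` pairs from
    proteins whose sliding diffusion coefficient was measured.  Each D is
    inverted to a roughness sigma (k_B*T); the return value is the
    Pearson r between chi and sigma together with the per-record sigmas.
    The model predicts a positive correlation (sigma = chi * sigma_max).
    """
    records = list(records)
    if len(records) < 3:
        raise InvalidParameterError(
            f"need >= 3 records for a correlation, got {len(records)}")
    chis = np.array([float(c) for c, _ in records])
    sigmas = np.array([roughness_from_experimental_d1d(float(d), params)
                       for _, d in records])
    if np.ptp(chis) == 0:
        raise InvalidParameterError(
            "chi is constant across records; correlation undefined")
    if np.ptp(sigmas) == 0:
        raise InvalidParameterError(
            "sigma is constant across records; correlation undefined")
    r, _ = pearsonr(chis, sigmas)
    return float(r), sigmas
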