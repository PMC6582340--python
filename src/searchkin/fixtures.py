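"""Synthetic complexes and parameter presets for testing and examples.

``make_toy_complex`` writes small idealized protein-DNA complexes (as both
PDB and mmCIF with identical coordinates) whose contact sets and
similarity indices are known by construction, so every structural module
can be exercised without downloading real crystal structures.  Atom
placements are idealized — consumers of these files are all
distance-based, so no stereochemistry is enforced.

``figure_presets`` returns the parameter sets of the standard trade-off
scans (the chi scans at fixed E_ns/dG_max/sigma_max and the E_ns/dG_max
scans at fixed chi) so examples and tests reproduce the same study
conditions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import InvalidParameterError
from .kinetics import LandscapeParameters, ModelParameters

__all__ = [
    "ResiduePlacement", "ToyComplexSpec", "make_toy_complex",
    "toy_complex_spec", "TOY_PRESETS", "FigurePreset", "figure_presets",
    "FIGURE_PRESETS",
]


@dataclass(frozen=True)
class ResiduePlacement:
    """One residue to synthesize: name, chain, number and its atoms."""

    name: str
    chain: str
    seq_number: int
    atoms: tuple[tuple[str, tuple[float, float, float]], ...]


@dataclass(frozen=True)
class ToyComplexSpec:
    """Deterministic recipe for a synthetic protein-DNA complex."""

    name: str
    protein: tuple[ResiduePlacement, ...]
    dna: tuple[ResiduePlacement, ...]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        ids = [(p.chain, p.seq_number) for p in self.protein + self.dna]
        if len(ids) != len(set(ids)):
            raise InvalidParameterError(
                f"toy complex {self.name!r}: duplicate residue ids")


def _element_of(atom_name: str) -> str:
    return atom_name.strip("0123456789'")[0]


def _gemmi_structure(spec: ToyComplexSpec) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = spec.name
    model = gemmi.Model(1)
    chains: dict[str, gemmi.Chain] = {}
    for placement in spec.protein + spec.dna:
        ch = chains.get(placement.chain)
        if ch is None:
            ch = gemmi.Chain(placement.chain)
            chains[placement.chain] = ch
        res = gemmi.Residue()
        res.name = placement.name
        res.seqid = gemmi.SeqId(placement.seq_number, " ")
        res.het_flag = "A"
        for atom_name, (x, y, z) in placement.atoms:
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element(_element_of(atom_name))
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 10.0
            res.add_atom(atom)
        ch.add_residue(res)
    for ch in chains.values():
        model.add_chain(ch)
    st.add_model(model)
    st.setup_entities()
    return st


def make_toy_complex(spec: ToyComplexSpec, out_dir,
                     formats: tuple[str, ...] = ("pdb", "cif")
                     ) -> dict[str, Path]:
    """Write the complex; returns ``{"pdb": path, "cif": path}``.

    Both formats carry identical coordinates; regeneration is byte-stable
    for a fixed spec.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    st = _gemmi_structure(spec)
    paths: dict[str, Path] = {}
    if "pdb" in formats:
        p = out_dir / f"{spec.name}.pdb"
        st.write_pdb(str(p))
        paths["pdb"] = p
    if "cif" in formats:
        p = out_dir / f"{spec.name}.cif"
        st.make_mmcif_document().write_file(str(p))
        paths["cif"] = p
    return paths


def _dg_residue(chain: str, seq: int, x0: float) -> ResiduePlacement:
    """Idealized guanine nucleotide: base N/O atoms near (x0, 0, 0),
    sugar-phosphate backbone below."""
    return ResiduePlacement("DG", chain, seq, (
        ("O6", (x0, 0.0, 0.0)),
        ("N7", (x0 + 1.3, -0.7, 0.0)),
        ("N1", (x0 - 1.2, -0.8, 0.0)),
        ("C6", (x0, -1.2, 0.0)),
        ("N9", (x0 + 1.0, -2.4, 0.0)),
        ("C1'", (x0 + 1.5, -3.8, 0.0)),
        ("O4'", (x0 + 0.6, -4.9, 0.0)),
        ("C4'", (x0 + 1.4, -6.0, 0.0)),
        ("O3'", (x0 + 0.8, -7.3, 0.0)),
        ("P", (x0 + 1.6, -8.7, 0.0)),
        ("OP1", (x0 + 2.9, -8.9, 0.6)),
        ("OP2", (x0 + 0.7, -9.8, 0.5)),
    ))


def _arg(chain: str, seq: int, tip: tuple[float, float, float]
         ) -> ResiduePlacement:
    x, y, z = tip
    return ResiduePlacement("ARG", chain, seq, (
        ("NH1", (x, y, z)),
        ("CZ", (x, y + 1.3, z)),
        ("NH2", (x + 1.1, y + 2.0, z)),
        ("CD", (x - 0.8, y + 2.3, z)),
        ("CB", (x - 0.5, y + 3.6, z)),
        ("CA", (x, y + 4.9, z)),
    ))


def _lys(chain: str, seq: int, tip: tuple[float, float, float]
         ) -> ResiduePlacement:
    x, y, z = tip
    return ResiduePlacement("LYS", chain, seq, (
        ("NZ", (x, y, z)),
        ("CE", (x, y + 1.5, z)),
        ("CD", (x, y + 3.0, z)),
        ("CB", (x, y + 4.4, z)),
        ("CA", (x, y + 5.8, z)),
    ))


def _glu(chain: str, seq: int, tip: tuple[float, float, float]
         ) -> ResiduePlacement:
    x, y, z = tip
    return ResiduePlacement("GLU", chain, seq, (
        ("OE1", (x, y, z)),
        ("CD", (x, y + 1.5, z)),
        ("CB", (x, y + 2.9, z)),
        ("CA", (x, y + 4.3, z)),
    ))


def _ser(chain: str, seq: int, tip: tuple[float, float, float]
         ) -> ResiduePlacement:
    x, y, z = tip
    return ResiduePlacement("SER", chain, seq, (
        ("OG", (x, y, z)),
        ("CB", (x, y + 1.4, z)),
        ("CA", (x, y + 2.8, z)),
    ))


def _plain(name: str, chain: str, seq: int,
           center: tuple[float, float, float]) -> ResiduePlacement:
    x, y, z = center
    return ResiduePlacement(name, chain, seq, (
        ("CA", (x, y, z)),
        ("CB", (x, y + 1.4, z)),
    ))


def _arg_on_guanine() -> ToyComplexSpec:
    # ARG guanidinium NH1 donates to guanine O6 at 3.0 A (specific contact);
    # LYS NZ kept at 6.0 A from the nearest base atom (non-contact patch).
    return ToyComplexSpec(
        name="arg-on-guanine",
        protein=(
            _arg("A", 1, (0.0, 3.0, 0.0)),
            _lys("A", 2, (3.0, 5.2, 0.0)),
        ),
        dna=(
            _dg_residue("B", 1, 0.0),
            _dg_residue("B", 2, 6.5),
        ),
    )


def _symmetric_dipole() -> ToyComplexSpec:
    # Neutral SER is the only specific contact; a +1 LYS and a -1 GLU sit
    # mirror-symmetrically about it, so chi = 0 exactly.
    lys = ResiduePlacement("LYS", "A", 2, (
        ("NZ", (4.0, 3.0, 0.0)),
        ("CE", (5.1, 4.0, 0.0)),
        ("CA", (6.4, 5.0, 0.0)),
    ))
    glu = ResiduePlacement("GLU", "A", 3, (
        ("OE1", (-4.0, 3.0, 0.0)),
        ("CD", (-5.1, 4.0, 0.0)),
        ("CA", (-6.4, 5.0, 0.0)),
    ))
    return ToyComplexSpec(
        name="symmetric-dipole",
        protein=(_ser("A", 1, (0.0, 3.0, 0.0)), lys, glu),
        dna=(_dg_residue("B", 1, 0.0),),
    )


def _patch_overlap() -> ToyComplexSpec:
    # 3 specific contacts (ARG, LYS, SER over consecutive bases) embedded in
    # a 5-lysine positive patch, with a sprinkling of acidic and neutral
    # residues farther out; 20 protein residues in total.  Coordinates are
    # fixed (seeded jitter on the filler shell only).
    rng = np.random.default_rng(2024)
    protein: list[ResiduePlacement] = [
        _arg("A", 1, (0.0, 3.0, 0.0)),
        _lys("A", 2, (4.5, 3.2, 0.0)),
        _ser("A", 3, (9.0, 3.0, 0.0)),
        # the positive patch around the contacts
        _lys("A", 4, (-3.5, 5.5, 2.0)),
        _lys("A", 5, (1.5, 6.5, 3.0)),
        _lys("A", 6, (6.0, 6.5, -2.5)),
        _lys("A", 7, (10.5, 5.5, 2.5)),
        _lys("A", 8, (13.5, 5.0, -1.5)),
        # acidic residues at the patch rim
        _glu("A", 9, (-6.0, 7.0, -3.0)),
        _glu("A", 10, (15.5, 7.5, 3.0)),
        ResiduePlacement("ASP", "A", 11, (
            ("OD1", (4.0, 10.5, 4.0)),
            ("CG", (4.0, 12.0, 4.0)),
            ("CA", (4.0, 13.4, 4.0)),
        )),
    ]
    # one neutral-by-default histidine inside the patch (its charge flips
    # under the "his+1" scheme, pulling chi up)
    protein.append(_plain("HIS", "A", 12, (2.0, 8.0, -3.0)))
    filler_names = ("ALA", "THR", "PHE", "GLY", "VAL",
                    "LEU", "ILE", "TYR")
    for k, name in enumerate(filler_names):
        angle = 2.0 * np.pi * k / len(filler_names)
        jitter = rng.uniform(-0.3, 0.3, size=3)
        center = (4.5 + 14.0 * np.cos(angle) + jitter[0],
                  12.0 + 4.0 * np.sin(angle) + jitter[1],
                  6.0 * np.sin(angle) + jitter[2])
        protein.append(_plain(name, "A", 13 + k, center))
    dna = tuple(_dg_residue("B", i + 1, 4.5 * i) for i in range(4))
    return ToyComplexSpec(name="patch-overlap",
                          protein=tuple(protein), dna=dna,
                          rng_seed=2024)


TOY_PRESETS = {
    "arg-on-guanine": _arg_on_guanine,
    "symmetric-dipole": _symmetric_dipole,
    "patch-overlap": _patch_overlap,
}


def toy_complex_spec(preset: str) -> ToyComplexSpec:
    """Return a named toy-complex recipe (deterministic)."""
    try:
        return TOY_PRESETS[preset]()
    except KeyError:
        raise InvalidParameterError(
            f"unknown toy preset {preset!r}; known: {sorted(TOY_PRESETS)}"
        ) from None


@dataclass(frozen=True)
class FigurePreset:
    """Parameter set of one standard trade-off scan.

    ``scan_variable`` names the x-axis; ``landscapes`` are the parameter
    templates of the individual curves (their ``scan_variable`` field is
    overridden along ``grid``).  The 3D excursion time is a free parameter
    of the model; each preset records the value it uses in ``params``
    (0 s — the pure-sliding bound — for the chi scans, a positive value
    for the E_ns scans where the round-count penalty matters).
    """

    name: str
    params: ModelParameters
    landscapes: tuple[LandscapeParameters, ...]
    grid: np.ndarray
    scan_variable: str
    description: str


def figure_presets(name: str) -> FigurePreset:
    """Parameter presets of the standard scans (chi grids at 0.01)."""
    try:
        factory = FIGURE_PRESETS[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown figure preset {name!r}; known: "
            f"{sorted(FIGURE_PRESETS)}") from None
    return factory()


def _chi_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 10)


def _params(genome_length: float = 5.0e6) -> ModelParameters:
    return ModelParameters(genome_length=genome_length, tau_3d=0.0)


def _fig2c() -> FigurePreset:
    return FigurePreset(
        name="fig2c", params=_params(),
        landscapes=(LandscapeParameters(chi=0.0, dg_max=10.0, e_ns=9.0,
                                        sigma_max=5.0),),
        grid=_chi_grid(), scan_variable="chi",
        description="tau_R surface over (sigma, dG) along the chi diagonal; "
                    "dG_max=10, sigma_max=5, E_ns=9 kT")


def _fig3a() -> FigurePreset:
    return FigurePreset(
        name="fig3a", params=_params(),
        landscapes=tuple(LandscapeParameters(chi=0.0, dg_max=5.0, e_ns=e,
                                             sigma_max=5.0)
                         for e in (5.0, 10.0, 15.0)),
        grid=_chi_grid(), scan_variable="chi",
        description="tau_1D vs chi for E_ns = 5, 10, 15 kT (dG_max=5)")


def _fig3b() -> FigurePreset:
    return FigurePreset(
        name="fig3b", params=_params(),
        landscapes=tuple(LandscapeParameters(chi=0.0, dg_max=g, e_ns=5.0,
                                             sigma_max=5.0)
                         for g in (5.0, 10.0)),
        grid=_chi_grid(), scan_variable="chi",
        description="S->R transition time vs chi for dG_max = 5, 10 kT")


def _fig3c() -> FigurePreset:
    return FigurePreset(
        name="fig3c", params=_params(),
        landscapes=(
            LandscapeParameters(chi=0.0, dg_max=0.0, e_ns=5.0, sigma_max=5.0),
            LandscapeParameters(chi=0.0, dg_max=10.0, e_ns=5.0, sigma_max=0.0),
            LandscapeParameters(chi=0.0, dg_max=5.0, e_ns=5.0, sigma_max=5.0),
        ),
        grid=_chi_grid(), scan_variable="chi",
        description="tau_R vs chi: barrierless (dG_max=0), smooth "
                    "(sigma_max=0, dG_max=10), and mixed (5, 5); "
                    "E_ns=5 kT, M=5e6")


#: 3D excursion time used by the E_ns scans: ~tau0*e^6, so the 1D/3D
#: balance point (tau_1D ~ tau_3D) falls mid-range of the scanned E_ns
#: and the round-count penalty at weak non-specific binding is visible
TAU_3D_ENS_SCAN = 4.7e-5


def _fig4a() -> FigurePreset:
    return FigurePreset(
        name="fig4a",
        params=ModelParameters(genome_length=5.0e6, tau_3d=TAU_3D_ENS_SCAN),
        landscapes=tuple(
            LandscapeParameters(chi=chi, dg_max=g, e_ns=0.0, sigma_max=5.0)
            for g in (2.0, 10.0) for chi in (0.2, 0.4)),
        grid=np.round(np.arange(0.0, 20.0 + 1e-9, 0.25), 10),
        scan_variable="e_ns",
        description="tau_R vs E_ns at chi = 0.2/0.4 for a low and a high "
                    "transition barrier (dG_max = 2, 10 kT)")


def _fig4b() -> FigurePreset:
    return FigurePreset(
        name="fig4b",
        params=ModelParameters(genome_length=5.0e6, tau_3d=TAU_3D_ENS_SCAN),
        landscapes=tuple(
            LandscapeParameters(chi=chi, dg_max=0.0, e_ns=e, sigma_max=5.0)
            for e in (5.0, 10.0) for chi in (0.2, 0.4)),
        grid=np.round(np.arange(0.0, 15.0 + 1e-9, 0.25), 10),
        scan_variable="dg_max",
        description="tau_R vs dG_max at chi = 0.2/0.4 for E_ns = 5, 10 kT")


FIGURE_PRESETS = {
    "fig2c": _fig2c, "fig3a": _fig3a, "fig3b": _fig3b, "fig3c": _fig3c,
    "fig4a": _fig4a, "fig4b": _fig4b,
}
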