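"""Seeded generators for toy complexes and two-state trajectories.

These fixtures encode the *statistical* structure the analyses assume —
not force-field physics: a cofactor inventory matching the full Rnf
complement (8+2 [4Fe4S] + the AE1 [2Fe2S] = 42 Fe; 3 FMN + 1 RBF), four
cysteines ligating AE1 at bonding distance, a membrane slab with an
optional bore for the pathway analysis, and trajectories whose B8–AE1
distance switches between Gaussian modes at ≈17 Å (inward) and ≈24 Å
(outward) under a two-state Markov chain, with redox- and
conformation-conditional Na⁺ occupancy of the buried site and a
state-dependent R67–E115 ion pair.  Every stochastic output is a pure
function of the seed, and each generator writes a ground-truth manifest
so the analysis layer can be tested by parameter recovery.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
import yaml

from .traj_analysis import TrajectoryEnsemble

__all__ = [
    "SyntheticConfig",
    "ToyComplexSpec",
    "make_toy_complex",
    "make_two_state_trajectory",
    "make_cycle_params",
    "trajectory_to_csv",
    "trajectory_from_csv",
]


@dataclass
class SyntheticConfig:
    """Generator parameters for the two-state trajectory fixture.

    Defaults encode the study conditions: distance modes at 17/24 Å with
    0.8 Å positional noise, dwell probabilities giving a 0.6 stationary
    inward fraction, buried-site Na⁺ occupancy 0.8 with AE1 reduced vs 0.2
    oxidized, and an ion pair mostly closed inward (open 0.2) but open in
    the outward state (0.8).
    """

    seed: int = 0
    n_frames: int = 4000
    state_means_A: dict = field(
        default_factory=lambda: {"inward": 17.0, "outward": 24.0}
    )
    state_noise_A: float = 0.8
    dwell_p: dict = field(
        default_factory=lambda: {"inward": 0.97, "outward": 0.955}
    )
    ion_count: int = 4
    p_reduced: float = 0.5
    buried_site_occupancy: dict = field(
        default_factory=lambda: {
            ("inward", "reduced"): 0.8,
            ("inward", "oxidized"): 0.2,
            ("outward", "reduced"): 0.7,
            ("outward", "oxidized"): 0.2,
        }
    )
    ion_pair_open_p: dict = field(
        default_factory=lambda: {"inward": 0.2, "outward": 0.8}
    )
    box_half_xy_A: float = 15.0
    solvent_half_z_A: float = 22.0
    gate_open_mean_A: float = 11.0
    gate_closed_mean_A: float = 4.5
    gate_noise_A: float = 0.5
    ion_pair_closed_A: float = 3.0
    ion_pair_open_A: float = 8.0

    def __post_init__(self) -> None:
        for p in list(self.dwell_p.values()) + list(
            self.buried_site_occupancy.values()
        ) + list(self.ion_pair_open_p.values()) + [self.p_reduced]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if any(m <= 0 for m in self.state_means_A.values()):
            raise ValueError("distance means must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    def stationary_inward_fraction(self) -> float:
        """Stationary inward probability of the two-state chain."""
        a = 1.0 - self.dwell_p["inward"]   # inward -> outward
        b = 1.0 - self.dwell_p["outward"]  # outward -> inward
        if a + b == 0:
            raise ValueError("dwell_p = 1 for both states: chain never mixes")
        return b / (a + b)


# ---------------------------------------------------------------------------
# toy complex


@dataclass
class ToyComplexSpec:
    """Layout parameters of the toy structure (Å; z is the membrane normal)."""

    bore: bool = True
    bore_radius_A: float = 4.5
    bore_center_xy: tuple[float, float] = (8.0, 8.0)
    slab_half_xy_A: float = 14.0
    slab_half_z_A: float = 12.0
    slab_spacing_A: float = 2.0
    clash_tolerance_A: float = 1.0


def _sf4_atoms(center: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Idealized [4Fe4S] cubane: Fe and S on interpenetrating tetrahedra."""
    t = 1.35 / np.sqrt(3.0)
    fe_dirs = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) * t
    s_dirs = -fe_dirs * (1.65 / 1.35)
    atoms = []
    for k, d in enumerate(fe_dirs, 1):
        atoms.append((f"FE{k}", "FE", center + d))
    for k, d in enumerate(s_dirs, 1):
        atoms.append((f"S{k}", "S", center + d))
    return atoms


def _fes_atoms(center: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Idealized [2Fe2S] rhombus in the xy plane."""
    return [
        ("FE1", "FE", center + np.array([-1.35, 0.0, 0.0])),
        ("FE2", "FE", center + np.array([1.35, 0.0, 0.0])),
        ("S1", "S", center + np.array([0.0, 1.73, 0.0])),
        ("S2", "S", center + np.array([0.0, -1.73, 0.0])),
    ]


def _flavin_atoms(center: np.ndarray) -> list[tuple[str, str, np.ndarray]]:
    """Minimal isoalloxazine-ring stand-in (planar hexagon + ring N)."""
    names = ["N5", "C4A", "C4", "N3", "C2", "N1", "C9A", "N10"]
    elements = ["N", "C", "C", "N", "C", "N", "C", "N"]
    ang = np.linspace(0, 2 * np.pi, len(names), endpoint=False)
    atoms = []
    for name, el, a in zip(names, elements, ang):
        pos = center + 1.4 * np.array([np.cos(a), np.sin(a), 0.0])
        atoms.append((name, el, pos))
    return atoms


def _residue_atoms(
    kind: str, anchor: np.ndarray, direction: np.ndarray | None = None
) -> list[tuple[str, str, np.ndarray]]:
    """Minimal amino-acid stand-ins with the functionally relevant atoms.

    For cysteines the backbone extends along `direction` (away from the
    coordinated metal) so that symmetric ligand sets do not collide.
    """
    if kind == "CYS":
        u = np.asarray(direction, float)
        u = u / np.linalg.norm(u)
        return [
            ("N", "N", anchor + 4.8 * u),
            ("CA", "C", anchor + 3.3 * u),
            ("CB", "C", anchor + 1.8 * u),
            ("SG", "S", anchor),
        ]
    if kind == "LEU":
        return [
            ("CA", "C", anchor + [0.0, 3.0, 0.0]),
            ("CB", "C", anchor + [0.0, 1.5, 0.0]),
            ("CD1", "C", anchor),
        ]
    if kind == "ARG":
        return [
            ("CZ", "C", anchor + [0.0, 1.33, 0.0]),
            ("NH1", "N", anchor),
            ("NH2", "N", anchor + [1.15, 2.0, 0.0]),
        ]
    if kind == "GLU":
        return [
            ("CD", "C", anchor + [0.0, 1.25, 0.0]),
            ("OE1", "O", anchor),
            ("OE2", "O", anchor + [1.05, 1.95, 0.0]),
        ]
    raise ValueError(kind)


def make_toy_complex(
    spec: ToyComplexSpec | None = None, out_dir: str | Path | None = None
):
    """Build the toy complex; optionally write toy_complex.pdb + manifest.

    Returns (gemmi.Structure, manifest dict).  The complex carries
    10 SF4 + 1 FES + 3 FMN + 1 RBF, four AE1-ligating cysteines at 2.3 Å
    Fe–S distance, gating and ion-pair residues, and a membrane slab with
    an optional bore.  The layout is deterministic (no randomness).
    """
    spec = spec or ToyComplexSpec()
    st = gemmi.Structure()
    st.name = "toy Rnf complex"
    model = gemmi.Model("1")

    chains: dict[str, gemmi.Chain] = {}

    def add_residue(chain_name, resname, resseq, atoms, het):
        if chain_name not in chains:
            chains[chain_name] = gemmi.Chain(chain_name)
        res = gemmi.Residue()
        res.name = resname
        res.seqid = gemmi.SeqId(resseq, " ")
        res.het_flag = "H" if het else "A"
        for name, el, pos in atoms:
            at = gemmi.Atom()
            at.name = name
            at.element = gemmi.Element(el)
            at.pos = gemmi.Position(*np.asarray(pos, float))
            res.add_atom(at)
        chains[chain_name].add_residue(res)

    placed: list[np.ndarray] = []  # flat positions, for slab carving
    residue_groups: list[np.ndarray] = []  # per-residue, for the clash check

    def register(atoms):
        pts = np.array([np.asarray(pos, float) for _, _, pos in atoms])
        placed.extend(pts)
        residue_groups.append(pts)

    # AE1 [2Fe2S] at the membrane centre + four ligating cysteines (SG at
    # 2.3 Å from an Fe, reproducing the C25/C113 (A) and C25/C108 (E) motif)
    ae1 = _fes_atoms(np.zeros(3))
    add_residue("A", "FES", 201, ae1, het=True)
    register(ae1)
    fe1 = np.array([-1.35, 0.0, 0.0])
    fe2 = np.array([1.35, 0.0, 0.0])
    cys_sites = [
        ("A", 25, fe1 + 2.3 * np.array([-0.7, 0.5, 0.51]) / np.linalg.norm([0.7, 0.5, 0.51])),
        ("A", 113, fe1 + 2.3 * np.array([-0.7, -0.5, -0.51]) / np.linalg.norm([0.7, 0.5, 0.51])),
        ("E", 25, fe2 + 2.3 * np.array([0.7, 0.5, -0.51]) / np.linalg.norm([0.7, 0.5, 0.51])),
        ("E", 108, fe2 + 2.3 * np.array([0.7, -0.5, 0.51]) / np.linalg.norm([0.7, 0.5, 0.51])),
    ]
    ligand_truth = []
    for (chain, resseq, sg), fe in zip(cys_sites, (fe1, fe1, fe2, fe2)):
        atoms = _residue_atoms("CYS", sg, direction=sg - fe)
        add_residue(chain, "CYS", resseq, atoms, het=False)
        register(atoms)
        ligand_truth.append([chain, "CYS", resseq])

    # RnfB chain: B8 cluster near the membrane surface (placed so that its
    # edge-to-edge distance to AE1 is ~17 Å, the inward-state value), with
    # B7..B1 stacked above towards the Fd docking region
    sf4_centers = {"B8": np.array([0.0, 0.0, 17.95])}
    for k in range(7, 0, -1):
        sf4_centers[f"B{k}"] = np.array([0.0, 0.0, 17.95 + 12.0 * (8 - k)])
    # RnfC clusters C1/C2 + FMN_C, laterally offset on the cytoplasmic side
    sf4_centers["C1"] = np.array([12.0, 0.0, 30.0])
    sf4_centers["C2"] = np.array([12.0, 0.0, 42.0])
    for idx, (label, c) in enumerate(sf4_centers.items(), start=301):
        chain = "B" if label.startswith("B") else "C"
        atoms = _sf4_atoms(c)
        add_residue(chain, "SF4", idx, atoms, het=True)
        register(atoms)

    flavins = {
        ("C", "FMN", 401): np.array([12.0, 0.0, 52.0]),
        ("G", "FMN", 402): np.array([0.0, -6.0, -14.5]),
        ("D", "FMN", 403): np.array([10.0, -6.0, -10.0]),
        ("D", "RBF", 404): np.array([12.0, -4.0, 2.0]),
    }
    for (chain, resname, resseq), c in flavins.items():
        atoms = _flavin_atoms(c)
        add_residue(chain, resname, resseq, atoms, het=True)
        register(atoms)

    # gating leucines: intracellular pair (top leaflet), extracellular (bottom)
    gate_sites = [
        ("A", "LEU", 108, np.array([-3.0, 6.0, 9.0])),
        ("E", "LEU", 22, np.array([3.0, 6.0, 9.0])),
        ("E", "LEU", 103, np.array([-3.0, 6.0, -9.0])),
        ("A", "LEU", 22, np.array([3.0, 6.0, -9.0])),
    ]
    for chain, resname, resseq, pos in gate_sites:
        atoms = _residue_atoms(resname, pos)
        add_residue(chain, resname, resseq, atoms, het=False)
        register(atoms)

    # R67–E115 ion pair near the cytosolic mouth
    arg = _residue_atoms("ARG", np.array([-6.0, -5.0, 11.0]))
    glu = _residue_atoms("GLU", np.array([-6.0, -5.0, 14.2]))
    add_residue("E", "ARG", 67, arg, het=False)
    add_residue("E", "GLU", 115, glu, het=False)
    register(arg)
    register(glu)

    # inter-residue clash check before adding the slab (bonded contacts
    # inside a residue are allowed; distinct groups must not interpenetrate,
    # except for the deliberate cysteine–cluster coordination bonds)
    pts = np.array(placed)
    from scipy.spatial.distance import cdist

    for ia in range(len(residue_groups)):
        for ib in range(ia + 1, len(residue_groups)):
            d = cdist(residue_groups[ia], residue_groups[ib]).min()
            if d < spec.clash_tolerance_A:
                raise ValueError(
                    "overlapping placements in toy complex "
                    f"(inter-residue distance {d:.2f} Å < "
                    f"{spec.clash_tolerance_A} Å)"
                )

    # membrane slab of dummy carbons, carved around the bore and any
    # placed atom so that nothing clashes
    n_slab = 0
    g = np.arange(-spec.slab_half_xy_A, spec.slab_half_xy_A + 1e-9,
                  spec.slab_spacing_A)
    gz = np.arange(-spec.slab_half_z_A, spec.slab_half_z_A + 1e-9,
                   spec.slab_spacing_A)
    bx, by = spec.bore_center_xy
    slab_atoms = []
    for x in g:
        for y in g:
            in_bore = spec.bore and (x - bx) ** 2 + (y - by) ** 2 <= spec.bore_radius_A**2
            if in_bore:
                continue
            for z in gz:
                p = np.array([x, y, z])
                if np.min(np.sum((pts - p) ** 2, axis=1)) < 9.0:
                    continue
                slab_atoms.append((f"C{len(slab_atoms) + 1}", "C", p))
    # split the slab into residues of <= 90 atoms to stay within PDB limits
    for start in range(0, len(slab_atoms), 90):
        batch = [
            (f"C{i + 1}", el, pos)
            for i, (_, el, pos) in enumerate(slab_atoms[start : start + 90])
        ]
        add_residue("M", "DUM", 501 + start // 90, batch, het=True)
    n_slab = len(slab_atoms)

    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()

    b8_edge = float(
        np.min(
            np.linalg.norm(
                np.array([p for _, _, p in ae1])[:, None, :]
                - np.array([p for _, _, p in _sf4_atoms(sf4_centers["B8"])])[None],
                axis=-1,
            )
        )
    )
    manifest = {
        "counts": {"SF4": 10, "FES": 1, "FMN": 3, "RBF": 1},
        "total_fe": 4 * 10 + 2 * 1,
        "ae1_id": "A/FES201",
        "b8_id": "B/SF4301",
        "b8_ae1_edge_A": b8_edge,
        "ae1_ligands": ligand_truth,
        "n_slab_atoms": n_slab,
        "bore": spec.bore,
        "bore_center_xy": list(spec.bore_center_xy),
        "bore_radius_A": spec.bore_radius_A,
        "slab_z_bounds": [-spec.slab_half_z_A, spec.slab_half_z_A],
        "n_atoms": sum(
            len(res) for ch in chains.values() for res in ch
        ),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        st.write_pdb(str(out_dir / "toy_complex.pdb"))
        (out_dir / "toy_complex.manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return st, manifest


# ---------------------------------------------------------------------------
# two-state trajectory


def make_two_state_trajectory(config: SyntheticConfig | None = None):
    """Generate the two-conformation trajectory fixture.

    Returns (TrajectoryEnsemble, manifest dict).  The manifest carries the
    per-frame ground truth (conformation, AE1 redox flag, buried-site
    occupancy, ion-pair state) and the generator parameters, so every
    analysis result can be compared against its generating value.
    """
    cfg = config or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_frames
    states = ("inward", "outward")
    if all(cfg.dwell_p[s] >= 1.0 for s in states) and n > 1:
        raise ValueError("dwell_p = 1 in both states cannot mix conformations")

    # conformation sequence: 2-state Markov chain started from stationarity
    pi_in = cfg.stationary_inward_fraction()
    conf = np.empty(n, dtype=object)
    conf[0] = "inward" if rng.random() < pi_in else "outward"
    for t in range(1, n):
        stay = cfg.dwell_p[conf[t - 1]]
        conf[t] = conf[t - 1] if rng.random() < stay else (
            "outward" if conf[t - 1] == "inward" else "inward"
        )

    redox = np.where(rng.random(n) < cfg.p_reduced, "reduced", "oxidized")
    occupied = np.array(
        [
            rng.random() < cfg.buried_site_occupancy[(c, r)]
            for c, r in zip(conf, redox)
        ]
    )
    pair_open = np.array(
        [rng.random() < cfg.ion_pair_open_p[c] for c in conf]
    )

    # roster: AE1 marker, B8 marker, 4 gate atoms, 2 ion-pair atoms, ions
    names = (
        ["AE1_FE", "B8_FE", "IC_A", "IC_B", "EC_A", "EC_B", "NH1", "OE1"]
        + [f"NA{k + 1}" for k in range(cfg.ion_count)]
    )
    elements = ["FE", "FE", "C", "C", "C", "C", "N", "O"] + ["NA"] * cfg.ion_count
    atoms = pd.DataFrame({"name": names, "element": elements})
    na0 = 8  # index of the first sodium

    coords = np.zeros((n, len(names), 3))
    d_b8 = np.array(
        [rng.normal(cfg.state_means_A[c], cfg.state_noise_A) for c in conf]
    )
    coords[:, 1, 2] = d_b8  # B8 marker along +z from the AE1 marker at origin

    def gate_distance(open_mask):
        mean = np.where(open_mask, cfg.gate_open_mean_A, cfg.gate_closed_mean_A)
        return rng.normal(mean, cfg.gate_noise_A)

    ic_open = conf == "inward"
    ec_open = conf == "outward"
    d_ic = gate_distance(ic_open)
    d_ec = gate_distance(ec_open)
    coords[:, 2] = np.column_stack([-d_ic / 2, np.full(n, 8.0), np.full(n, 6.0)])
    coords[:, 3] = np.column_stack([d_ic / 2, np.full(n, 8.0), np.full(n, 6.0)])
    coords[:, 4] = np.column_stack([-d_ec / 2, np.full(n, 8.0), np.full(n, -6.0)])
    coords[:, 5] = np.column_stack([d_ec / 2, np.full(n, 8.0), np.full(n, -6.0)])

    d_pair = np.where(pair_open, cfg.ion_pair_open_A, cfg.ion_pair_closed_A)
    d_pair = d_pair + rng.normal(0.0, 0.2, size=n)
    coords[:, 6] = np.column_stack([np.full(n, -8.0), -d_pair / 2, np.full(n, 10.0)])
    coords[:, 7] = np.column_stack([np.full(n, -8.0), d_pair / 2, np.full(n, 10.0)])

    # sodium ions: ion 0 sits in the buried site (near the AE1 origin) when
    # occupied, otherwise all ions are uniform in the solvent box
    half = cfg.box_half_xy_A
    zhalf = cfg.solvent_half_z_A
    for k in range(cfg.ion_count):
        coords[:, na0 + k, 0] = rng.uniform(-half, half, n)
        coords[:, na0 + k, 1] = rng.uniform(-half, half, n)
        # free ions stay out of the buried-site neighbourhood (|z| < 4 Å) so
        # occupancy recovery measures the generator flag, not chance passes
        zmag = rng.uniform(4.0, zhalf, n)
        zsign = np.where(rng.random(n) < 0.5, -1.0, 1.0)
        coords[:, na0 + k, 2] = zsign * zmag
    site_noise = rng.normal(0.0, 0.3, size=(n, 3))
    occ_idx = np.where(occupied)[0]
    coords[occ_idx, na0, :] = site_noise[occ_idx]

    groups = {
        "ae1": np.array([0]),
        "b8": np.array([1]),
        "gate_ic_a": np.array([2]),
        "gate_ic_b": np.array([3]),
        "gate_ec_a": np.array([4]),
        "gate_ec_b": np.array([5]),
        "ionpair_n": np.array([6]),
        "ionpair_o": np.array([7]),
        "sodium": np.arange(na0, na0 + cfg.ion_count),
        "buried_ion": np.array([na0]),
    }
    traj = TrajectoryEnsemble(coords=coords, atoms=atoms, groups=groups)

    manifest = {
        "seed": cfg.seed,
        "n_frames": n,
        "state_means_A": dict(cfg.state_means_A),
        "state_noise_A": cfg.state_noise_A,
        "stationary_inward_fraction": pi_in,
        "labels": conf.tolist(),
        "redox": redox.tolist(),
        "occupied": occupied.tolist(),
        "ion_pair_open": pair_open.tolist(),
        "buried_site_occupancy": {
            f"{c}|{r}": p for (c, r), p in cfg.buried_site_occupancy.items()
        },
        "ion_pair_open_p": dict(cfg.ion_pair_open_p),
    }
    return traj, manifest


def trajectory_to_csv(
    traj: TrajectoryEnsemble, manifest: dict, out_dir: str | Path
) -> None:
    """Write the columnar plain-text fixture (frame, atom, x, y, z) + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n_frames, n_atoms, _ = traj.coords.shape
    frame = np.repeat(np.arange(n_frames), n_atoms)
    atom = np.tile(np.arange(n_atoms), n_frames)
    flat = traj.coords.reshape(-1, 3)
    df = pd.DataFrame(
        {
            "frame": frame,
            "atom": atom,
            "name": np.tile(traj.atoms["name"].to_numpy(), n_frames),
            "x": flat[:, 0],
            "y": flat[:, 1],
            "z": flat[:, 2],
        }
    )
    df.to_csv(out_dir / "trajectory.csv", index=False, float_format="%.4f")
    meta = dict(manifest)
    meta["groups"] = {k: v.tolist() for k, v in traj.groups.items()}
    meta["atoms"] = traj.atoms.to_dict(orient="list")
    (out_dir / "trajectory.manifest.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n"
    )


def trajectory_from_csv(out_dir: str | Path) -> tuple[TrajectoryEnsemble, dict]:
    """Round-trip reader for the columnar fixture."""
    out_dir = Path(out_dir)
    df = pd.read_csv(out_dir / "trajectory.csv")
    meta = json.loads((out_dir / "trajectory.manifest.json").read_text())
    n_frames = int(df["frame"].max()) + 1
    n_atoms = int(df["atom"].max()) + 1
    coords = (
        df.sort_values(["frame", "atom"])[["x", "y", "z"]]
        .to_numpy(float)
        .reshape(n_frames, n_atoms, 3)
    )
    atoms = pd.DataFrame(meta["atoms"])
    groups = {k: np.asarray(v, int) for k, v in meta["groups"].items()}
    return TrajectoryEnsemble(coords=coords, atoms=atoms, groups=groups), meta


# ---------------------------------------------------------------------------
# cycle parameter presets


def make_cycle_params(
    preset: str = "default",
    out_path: str | Path | None = None,
    overrides: dict | None = None,
):
    """Emit a complete, closure-consistent pump-cycle parameter set.

    Presets: ``default`` (Fd −450 mV; break-even SMF 130 mV) and
    ``fd-low`` (Fd −500 mV, the low end of the ferredoxin range;
    break-even 180 mV).  ``custom`` starts from the default and applies
    overrides, then verifies cycle closure.
    """
    from .pump_cycle import CycleParams, build_canonical_cycle, cycle_closure_check

    if preset == "default":
        params = CycleParams()
    elif preset == "fd-low":
        params = CycleParams(fd_mV=-500.0)
    elif preset == "custom":
        params = CycleParams(**(overrides or {}))
    else:
        raise ValueError(f"unknown preset {preset!r}")

    model = build_canonical_cycle(params)
    residual = cycle_closure_check(model)
    if abs(residual) > 1e-6:
        raise ValueError(f"parameter set violates cycle closure: {residual:.3e}")

    payload = {"preset": preset, **asdict(params)}
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        Path(out_path).write_text(yaml.safe_dump(payload, sort_keys=True))
    return params
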