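"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (parameter block, seed): the same
inputs always produce the same output.  The generators emulate the
statistical structure the analysis assumes —

* two-transition melting curves whose triplex amplitude follows a
  single-site binding isotherm in TFO concentration,
* gel titrations with duplex-band depletion and a staining-bias term,
* lag + linear kinetic traces with replicate rate jitter,
* idealized three-strand helical coordinate sets with a controllable
  end-to-end radius taper (strain),
* promoter sequences with embedded polypurine tracts, and
* strain-modulation point sets drawn from a biphasic sigmoid —

so that every analysis stage can be exercised and calibrated without
measured data.  The isotherm assumes no TFO depletion (duplex target
far below Kd, as in the titrations being emulated), and the two melting
transitions are independent logistics rather than a coupled partition
function; see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from .affinity_analysis import GelLane, MeltCurve
from .kinetics_modulation import KineticTrace
from .sequence_screen import PromoterRecord, reverse_complement
from .triplex_geometry import Atom, StrainPoint, TriplexStructure, biphasic_sigmoid

DEFAULT_RAMP = np.arange(25.0, 95.0 + 1e-9, 0.5)    # C, qPCR-style melt ramp


# ---------------------------------------------------------------------------
# Parameter blocks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltParams:
    """Melt-titration generator parameters.

    Defaults mirror the characterized triplexes: duplex transition near
    50 C, triplex transition in the low 40s, Kd of order 1 uM, seven
    TFO concentrations spanning the isotherm including the zero-TFO
    reference, comparable transition amplitudes and 0.8 C logistic
    transition widths (the two derivative peaks stay cleanly resolved
    at the 8 C Tm separation, as in the emulated melts) and a few
    percent multiplicative instrument noise.  When
    ``concentrations_nM`` is None the titration brackets the isotherm
    with seven log-spaced concentrations centred on Kd (plus the zero
    reference), as a titration experiment would be designed.
    """

    kd_uM: float = 2.0
    tm_dup: float = 50.0
    tm_tri: float = 42.0
    width_dup: float = 0.8
    width_tri: float = 0.8
    amp_dup: float = 100.0
    amp_tri: float = 100.0
    baseline: float = 5.0
    noise_frac: float = 0.02
    n_replicates: int = 3
    concentrations_nM: tuple[float, ...] | None = None

    def resolved_concentrations(self) -> tuple[float, ...]:
        if self.concentrations_nM is not None:
            return self.concentrations_nM
        return titration_concentrations(self.kd_uM)


@dataclass(frozen=True)
class GelParams:
    """EMSA titration generator; staining_bias >= 1 shifts the apparent
    isotherm to kd/bias, emulating probe-affinity distortion."""

    kd_uM: float = 2.0
    staining_bias: float = 1.0
    duplex_scale: float = 1000.0
    noise_frac: float = 0.0
    concentrations_nM: tuple[float, ...] | None = None

    def resolved_concentrations(self) -> tuple[float, ...]:
        if self.concentrations_nM is not None:
            return self.concentrations_nM
        return titration_concentrations(self.kd_uM)


@dataclass(frozen=True)
class KineticsParams:
    """Lag + linear reporter kinetics, sampled every 5 min over 8 h."""

    rate: float = 5.0                   # a.u./min steady-state slope
    lag_min: float = 30.0
    plateau: float = 1e9                # effectively uncapped by default
    baseline: float = 10.0
    noise_sd: float = 2.0               # additive trace noise, a.u.
    rate_jitter_frac: float = 0.05      # multiplicative replicate-level rate sd (~5% CV)
    n_replicates: int = 3
    modulation_multiplier: float = 1.0
    t_end_min: float = 480.0
    dt_min: float = 5.0


@dataclass(frozen=True)
class HelixParams:
    """Idealized three-strand helix.

    Residue j of chain k places its C1' at radius ``radius[k] +
    taper*j/(n-1)``, phase ``phase_deg[k] + j*twist_deg`` and height
    ``j*rise``.  The Watson-Crick pyrimidine strand is written
    antiparallel (its 5'->3' residue order descends the helix axis).
    """

    n_residues: int = 15
    rise: float = 3.4                   # Å per step
    twist_deg: float = 32.7
    radius: tuple[float, float, float] = (6.1, 6.1, 6.1)  # purine, pyrimidine, tfo
    phase_deg: tuple[float, float, float] = (0.0, 120.0, 240.0)
    taper: float = 0.0                  # Å added to every radius at the 3' plane


@dataclass(frozen=True)
class PromoterParams:
    """Promoter with consensus boxes and one embedded polypurine tract.

    The random background forces a pyrimidine every 4th position on
    each strand so no background window can satisfy the scan
    thresholds, and the embedded tract is flanked by double
    interruptions on its purine strand so it cannot extend; the tract
    is then the unique discoverable TTS.
    """

    length: int = 120
    minus35_start: int = 20
    minus10_start: int = 43
    plus1_index: int = 56
    tts_length: int = 15
    tts_offset: int = 60                # sense-strand start of the tract
    tts_strand: str = "sense"           # "sense" | "template"
    tts_purity: float = 1.0             # purine fraction of the embedded tract


@dataclass(frozen=True)
class StrainParams:
    """Strain-modulation point generator: biphasic sigmoid with argmax
    ``peak_d`` over ``d_range`` plus additive Gaussian noise."""

    peak_d: float = 10.3
    baseline: float = 0.0
    amplitude: float = 120.0
    rise_width: float = 0.08
    fall_width: float = 0.08
    plateau_half_width: float = 0.15    # (d2-d1)/2 around the peak
    d_range: tuple[float, float] = (9.8, 11.2)
    n_points: int = 24
    noise_sd: float = 0.0


@dataclass(frozen=True)
class SyntheticScenario:
    """Bundle of all layer parameter blocks plus the master seed."""

    seed: int = 0
    melt: MeltParams = field(default_factory=MeltParams)
    gel: GelParams = field(default_factory=GelParams)
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    helix: HelixParams = field(default_factory=HelixParams)
    promoter: PromoterParams = field(default_factory=PromoterParams)
    strain: StrainParams = field(default_factory=StrainParams)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def titration_concentrations(kd_uM: float, n: int = 7, decades: float = 1.1) -> tuple[float, ...]:
    """Zero plus ``n`` log-spaced concentrations bracketing Kd.

    Spans ``kd * 10**(-decades .. +decades)`` so the bound fraction runs
    from ~7% to ~93%, as a well-designed titration would."""
    kd_nM = kd_uM * 1000.0
    factors = np.logspace(-decades, decades, n)
    return (0.0, *(float(kd_nM * f) for f in factors))


def bound_fraction(conc_nM: float, kd_uM: float) -> float:
    """Single-site isotherm f = c/(c + Kd), no ligand depletion."""
    kd_nM = kd_uM * 1000.0
    return conc_nM / (conc_nM + kd_nM) if conc_nM > 0 else 0.0


def gen_melt_titration(params: MeltParams, seed: int) -> list[MeltCurve]:
    """Two-transition melt curves across a TFO titration.

    F(T) = A_dup*sigma((tm_dup-T)/w_dup) + f(c)*A_tri*sigma((tm_tri-T)/w_tri)
    + baseline, with multiplicative Gaussian noise of sd ``noise_frac``.
    """
    if not params.tm_tri < params.tm_dup:
        raise ValueError("triplex transition must melt below the duplex one")
    concentrations = params.resolved_concentrations()
    if 0.0 not in concentrations:
        raise ValueError("concentration list must include the zero-TFO reference")
    rng = np.random.default_rng(seed)
    T = DEFAULT_RAMP
    curves = []
    for conc in concentrations:
        f = bound_fraction(conc, params.kd_uM)
        clean = (
            params.amp_dup * expit((params.tm_dup - T) / params.width_dup)
            + f * params.amp_tri * expit((params.tm_tri - T) / params.width_tri)
            + params.baseline
        )
        for rep in range(params.n_replicates):
            noisy = clean * (1.0 + params.noise_frac * rng.standard_normal(T.size))
            curves.append(MeltCurve(tfo_concentration=conc, temperatures=T.copy(),
                                    fluorescence=noisy))
    return curves


def gen_gel_lanes(params: GelParams, seed: int) -> list[GelLane]:
    """Duplex-depletion gel titration with a staining-bias term."""
    if params.staining_bias < 1:
        raise ValueError("staining_bias must be >= 1")
    rng = np.random.default_rng(seed)
    lanes = []
    kd_app = params.kd_uM / params.staining_bias
    for i, conc in enumerate(sorted(params.resolved_concentrations())):
        f_app = bound_fraction(conc, kd_app)
        duplex = params.duplex_scale * (1.0 - f_app)
        triplex = params.duplex_scale * f_app
        free_tfo = 0.05 * conc
        noise = 1.0 + params.noise_frac * rng.standard_normal(3)
        lanes.append(GelLane(
            lane_index=i + 1, tfo_concentration=conc,
            band_intensities={"duplex": max(duplex * noise[0], 0.0),
                              "triplex": max(triplex * noise[1], 0.0),
                              "free_tfo": max(free_tfo * noise[2], 0.0)},
        ))
    return lanes


def gen_kinetic_traces(
    params: KineticsParams, seed: int, condition: str = "purine_tfo",
    sample_id: str = "synthetic",
) -> list[KineticTrace]:
    """Lag + linear reporter traces with replicate-level rate jitter."""
    if params.n_replicates < 3:
        raise ValueError("need >=3 replicates")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.t_end_min + 1e-9, params.dt_min)
    traces = []
    for rep in range(params.n_replicates):
        rate = params.rate * params.modulation_multiplier
        if params.rate_jitter_frac > 0:
            rate *= 1.0 + params.rate_jitter_frac * rng.standard_normal()
        clean = params.baseline + np.minimum(
            rate * np.maximum(0.0, t - params.lag_min), params.plateau
        )
        noisy = clean + params.noise_sd * rng.standard_normal(t.size)
        traces.append(KineticTrace(sample_id=sample_id, condition=condition,
                                   replicate=rep, times=t.copy(), fluorescence=noisy))
    return traces


_CHAIN_SPECS = (
    # (chain_id, role, residue names cycled, is_rna, antiparallel)
    ("A", "wc_purine", ("DG", "DA"), False, False),
    ("B", "wc_pyrimidine", ("DC", "DT"), False, True),
    ("C", "tfo", ("C", "U"), True, False),
)


def gen_helix(params: HelixParams, seed: int = 0) -> TriplexStructure:
    """Idealized triplex helix with controllable end-to-end taper.

    Deterministic given parameters (the seed is accepted for interface
    uniformity).  The TFO chain carries O2' pseudo-atoms so role
    inference works on written PDB files; the pyrimidine strand's
    residues are emitted in 5'->3' order running down the helix axis
    (antiparallel to the purine strand).
    """
    n = params.n_residues
    if n < 2:
        raise ValueError("need >=2 residues per chain")
    atoms: list[Atom] = []
    roles = {}
    for k, (cid, role, names, is_rna, anti) in enumerate(_CHAIN_SPECS):
        roles[cid] = role
        for r in range(n):
            j = (n - 1 - r) if anti else r     # axial step of this residue
            radius = params.radius[k] + params.taper * j / (n - 1)
            ang = np.deg2rad(params.phase_deg[k] + j * params.twist_deg)
            x, y, z = radius * np.cos(ang), radius * np.sin(ang), j * params.rise
            atoms.append(Atom(cid, r + 1, names[r % len(names)], "C1'", x, y, z))
            if is_rna:
                atoms.append(Atom(cid, r + 1, names[r % len(names)], "O2'",
                                  x * 1.05, y * 1.05, z + 0.5))
    return TriplexStructure(atoms=tuple(atoms), roles=roles)


def write_helix_pdb(structure: TriplexStructure, path: str | Path) -> None:
    """Write a minimal PDB coordinate file for a generated helix."""
    import gemmi

    st = gemmi.Structure()
    st.name = "synthetic_triplex"
    model = gemmi.Model("1")
    by_chain: dict[str, list[Atom]] = {}
    for a in structure.atoms:
        by_chain.setdefault(a.chain_id, []).append(a)
    for cid, chain_atoms in by_chain.items():
        chain = gemmi.Chain(cid)
        by_res: dict[int, list[Atom]] = {}
        for a in chain_atoms:
            by_res.setdefault(a.residue_index, []).append(a)
        for rid in sorted(by_res):
            res = gemmi.Residue()
            res.name = by_res[rid][0].residue_name
            res.seqid = gemmi.SeqId(rid, " ")
            for a in by_res[rid]:
                atom = gemmi.Atom()
                atom.name = a.atom_name
                atom.pos = gemmi.Position(a.x, a.y, a.z)
                atom.element = gemmi.Element("O" if a.atom_name.startswith("O") else "C")
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


_HEXAMER_M35 = "TTGACA"
_HEXAMER_M10 = "TATAAT"


def gen_promoter(params: PromoterParams, seed: int, promoter_id: str = "synthetic") -> PromoterRecord:
    """Random promoter with consensus boxes and one embedded tract.

    Background positions i % 4 == 1 are forced pyrimidine and
    i % 4 == 3 forced purine, so every 15-nt background window carries
    >= 3 interruptions on either strand and cannot pass the scan
    thresholds; the embedded tract is then the unique discoverable TTS.
    """
    rng = np.random.default_rng(seed)
    n = params.length
    tts_end = params.tts_offset + params.tts_length
    if tts_end > n:
        raise ValueError("embedded TTS does not fit in the sequence")
    regions = [
        (params.minus35_start, params.minus35_start + 6),
        (params.minus10_start, params.minus10_start + 6),
        (params.tts_offset - 2, tts_end + 2),   # includes the blocking flanks
    ]
    for (s1, e1), (s2, e2) in zip(regions, regions[1:]):
        if s2 < e1:
            raise ValueError("overlap conflict between boxes and embedded TTS")

    seq = []
    for i in range(n):
        if i % 4 == 1:
            seq.append(rng.choice(list("CT")))
        elif i % 4 == 3:
            seq.append(rng.choice(list("AG")))
        else:
            seq.append(rng.choice(list("ACGT")))
    seq[params.minus35_start : params.minus35_start + 6] = _HEXAMER_M35
    seq[params.minus10_start : params.minus10_start + 6] = _HEXAMER_M10

    tract = []
    n_pyr = round((1.0 - params.tts_purity) * params.tts_length)
    pyr_pos = set(rng.choice(params.tts_length, size=n_pyr, replace=False).tolist()) if n_pyr else set()
    for i in range(params.tts_length):
        tract.append(rng.choice(list("CT")) if i in pyr_pos else rng.choice(list("AG")))
    tract_s = "".join(tract)
    if params.tts_strand == "template":
        tract_s = reverse_complement(tract_s)
    seq[params.tts_offset : tts_end] = tract_s
    # hard-block tract extension with a double interruption on the purine
    # strand immediately flanking the embedded tract ("CC" on the sense
    # strand for a sense tract, "AA" -> template "TT" for a template tract)
    block = "CC" if params.tts_strand == "sense" else "AA"
    lo, hi = params.tts_offset - 2, tts_end + 2
    if lo >= 0:
        seq[lo : lo + 2] = block
    if hi <= n:
        seq[hi - 2 : hi] = block

    return PromoterRecord(
        id=promoter_id, sequence="".join(seq),
        minus35_start=params.minus35_start, minus10_start=params.minus10_start,
        plus1_index=params.plus1_index,
    )


def gen_strain_points(params: StrainParams, seed: int) -> list[StrainPoint]:
    """Distance/modulation points from a biphasic sigmoid with known argmax."""
    if params.n_points < 5:
        raise ValueError("need >=5 points")
    rng = np.random.default_rng(seed)
    d = np.linspace(*params.d_range, params.n_points)
    d1 = params.peak_d - params.plateau_half_width
    d2 = params.peak_d + params.plateau_half_width
    y = biphasic_sigmoid(d, params.baseline, params.amplitude,
                         d1, params.rise_width, d2, params.fall_width)
    # symmetric rise/fall widths put the curve's argmax exactly at peak_d;
    # rescale so the injected amplitude is reached at the peak
    peak_val = float(biphasic_sigmoid(np.array([params.peak_d]), 0.0, 1.0,
                                      d1, params.rise_width, d2, params.fall_width)[0])
    if peak_val > 0 and params.amplitude != 0:
        y = params.baseline + (y - params.baseline) / peak_val
    y = y + params.noise_sd * rng.standard_normal(d.size)
    return [StrainPoint(triplex_id=f"s{i}", distance=float(di), modulation=float(yi))
            for i, (di, yi) in enumerate(zip(d, y))]
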