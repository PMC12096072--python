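"""Published reference measurements for the six characterized triplexes.

Three *E. coli* promoter-derived triplex target sites (poxBp1, safAp,
sraGp), each tested with a purine-motif (Pu) and a pyrimidine-motif
(Py) RNA third strand, were characterized by melting-based Kd
titration, in vitro transcription modulation in four TU geometries
(A-D), and structural modeling.  The values below are the printed
results of those experiments and serve as worked inputs for the
strain-optimum analysis (a fourth site, lrpp, formed no stable triplex
and has no entries).

Keys are ``"<promoter>_<motif>"`` with motif ``Pu`` or ``Py``.
"""

from __future__ import annotations

from .triplex_geometry import GeometryMetrics

TRIPLEX_IDS = ("poxBp1_Pu", "poxBp1_Py", "safAp_Pu", "safAp_Py", "sraGp_Pu", "sraGp_Py")

#: melting-route dissociation constants, uM (value, reported uncertainty).
KD_TM_UM: dict[str, tuple[float, float]] = {
    "safAp_Pu": (1.2, 0.2),
    "safAp_Py": (0.45, 0.06),
    "sraGp_Pu": (2.0, 1.0),
    "sraGp_Py": (19.0, 1.0),
    "poxBp1_Pu": (2.0, 0.2),
    "poxBp1_Py": (0.5, 0.1),
}

#: transcription modulation, % vs the no-TFO reference (value, sd), keyed by
#: TU geometry A-D.  A/B place the TTS downstream of the promoter consensus
#: (template/sense purine strand); C/D place it within the consensus.
MODULATION_PERCENT: dict[str, dict[str, tuple[float, float]]] = {
    "A": {
        "sraGp_Pu": (6.0, 6.0), "sraGp_Py": (120.0, 70.0),
        "poxBp1_Pu": (40.0, 70.0), "poxBp1_Py": (40.0, 10.0),
        "safAp_Pu": (-2.0, 4.0), "safAp_Py": (110.0, 30.0),
    },
    "B": {
        "sraGp_Pu": (-3.0, 8.0), "sraGp_Py": (34.0, 1.0),
        "poxBp1_Pu": (-30.0, 10.0), "poxBp1_Py": (19.0, 3.0),
        "safAp_Pu": (10.0, 20.0), "safAp_Py": (30.0, 10.0),
    },
    "C": {
        "sraGp_Pu": (-23.0, 8.0), "sraGp_Py": (-16.0, 2.0),
        "poxBp1_Pu": (-21.0, 9.0), "poxBp1_Py": (-10.0, 10.0),
        "safAp_Pu": (-20.0, 10.0), "safAp_Py": (-60.0, 10.0),
    },
    "D": {
        "sraGp_Pu": (-53.0, 6.0), "sraGp_Py": (8.0, 3.0),
        "poxBp1_Pu": (-30.0, 40.0), "poxBp1_Py": (-16.0, 6.0),
        "safAp_Pu": (50.0, 30.0), "safAp_Py": (70.0, 10.0),
    },
}

#: modeled terminal-plane distances, Å: L1 (5' plane), L2 (3' plane),
#: dL = |L1-L2|, L3 (helix length).
GEOMETRY_METRICS: dict[str, GeometryMetrics] = {
    "poxBp1_Pu": GeometryMetrics(L1=10.57, L2=9.98, dL=0.59, L3=47.84),
    "poxBp1_Py": GeometryMetrics(L1=10.33, L2=10.28, dL=0.05, L3=47.81),
    "safAp_Pu": GeometryMetrics(L1=10.66, L2=10.44, dL=0.22, L3=47.94),
    "safAp_Py": GeometryMetrics(L1=10.50, L2=10.33, dL=0.17, L3=47.89),
    "sraGp_Pu": GeometryMetrics(L1=11.14, L2=11.04, dL=0.10, L3=47.67),
    "sraGp_Py": GeometryMetrics(L1=10.91, L2=10.35, dL=0.56, L3=47.75),
}


def modulation_values(geometry: str = "A") -> dict[str, float]:
    """Per-triplex modulation percentages for one TU geometry."""
    return {k: v[0] for k, v in MODULATION_PERCENT[geometry].items()}
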