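"""Reference magnitudes for root epidermal cells.

These published measurement magnitudes parameterize the synthetic-data
generator and serve as inputs to worked examples: cytosolic volumes per
developmental zone under phosphate-replete and -starved growth, the
cyanide-assay uptake deltas for the apical zones, and typical steady-state
cytosolic Pi concentrations per zone.

Zones, ordered from the root apex: LRC (lateral root cap), MZ (meristematic),
TZ (transition), EZ (elongation), DZ (differentiation), MR (mature root).
"""

ZONES = ("LRC", "MZ", "TZ", "EZ", "DZ", "MR")

#: root-axis zones (the LRC flanks the apex and is not part of the
#: distance-from-tip profile)
AXIS_ZONES = ("MZ", "TZ", "EZ", "DZ", "MR")

#: cytosolic volume (mean, sd) in µm³ per (zone, growth condition)
CYTOSOL_VOLUME_UM3 = {
    ("MR", "replete"): (4976.0, 1856.0),
    ("MR", "starved"): (2419.0, 1074.0),
    ("DZ", "replete"): (4233.0, 834.0),
    ("DZ", "starved"): (2198.0, 917.0),
    ("EZ", "replete"): (3660.0, 1599.0),
    ("EZ", "starved"): (1735.0, 377.0),
    ("TZ", "replete"): (1213.0, 354.0),
    ("TZ", "starved"): (403.0, 131.0),
    ("MZ", "replete"): (473.0, 168.0),
    ("MZ", "starved"): (192.0, 97.0),
    ("LRC", "replete"): (810.0, 180.0),
    ("LRC", "starved"): (597.0, 98.0),
}

#: cyanide-assay uptake deltas (mean, sd), mM, Pi-starved roots; only the
#: apical zones show resolvable uptake
UPTAKE_DELTA_MM = {
    "LRC": (0.78, 0.07),
    "MZ": (0.84, 0.02),
    "TZ": (0.47, 0.07),
}

#: per-cell uptake amounts (mean, sd), fmol, volume-corrected
UPTAKE_AMOUNT_FMOL = {
    "LRC": (0.47, 0.12),
    "MZ": (0.16, 0.01),
    "TZ": (0.17, 0.03),
}

#: steady-state cytosolic Pi (mM) per zone, Pi-replete growth. TZ peaks near
#: 10 mM and MZ/MR sit near 4 mM; EZ/DZ are interpolated between them.
ZONE_MEAN_PI_MM = {
    "LRC": 5.0,
    "MZ": 4.0,
    "TZ": 10.0,
    "EZ": 7.0,
    "DZ": 6.0,
    "MR": 4.0,
}

#: starvation scales all zones roughly proportionally
STARVED_SCALE = 0.75

#: cyanide-only (metabolic recycling) plateau rises, mM: lower in the apical
#: zones, higher in the basal zones
RECYCLING_DELTA_MM = {
    "LRC": 0.50,
    "MZ": 0.47,
    "TZ": 0.55,
    "EZ": 1.2,
    "DZ": 1.2,
    "MR": 1.2,
}

#: sensor dissociation constant (mM) and its standard error, in vivo
KD_MM = 7.4
KD_SE_MM = 1.7


def zone_mean_pi(zone: str, condition: str = "replete") -> float:
    c = ZONE_MEAN_PI_MM[zone]
    return c * STARVED_SCALE if condition == "starved" else c
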