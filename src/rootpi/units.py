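"""Unit conventions used throughout the package.

One convention, fixed project-wide:

* volumes: 1 µm³ = 1 fL, so 1 pL = 1000 µm³
* amounts: 1 mM × 1 µm³ = 10⁻³ fmol
* concentrations are millimolar (mM) unless a name says otherwise
"""

UM3_PER_PL = 1000.0
DEFAULT_VOXEL_UM3 = 0.06


def um3_to_pl(volume_um3: float) -> float:
    """Convert a volume in µm³ to picoliters (1 pL = 1000 µm³)."""
    return volume_um3 / UM3_PER_PL


def pl_to_um3(volume_pl: float) -> float:
    return volume_pl * UM3_PER_PL


def amount_fmol(delta_mm: float, volume_um3: float) -> float:
    """Amount of solute (fmol) in ``volume_um3`` at concentration ``delta_mm``.

    1 mM × 1 µm³ = 10⁻¹⁸ mol·µm³/L × ... = 10⁻³ fmol.
    """
    return delta_mm * volume_um3 * 1e-3
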