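"""Physical constants and reference tables used across the package.

All scattering lengths are coherent neutron scattering lengths in fm
(1 fm = 1e-13 cm); volumes in cubic angstrom; SLDs in inverse square
angstrom. The residue table lists, per standard amino-acid residue as
incorporated in a peptide chain (i.e. minus one water of condensation),
the scattering length of the fully protonated residue, the number of
labile (solvent-exchangeable) hydrogens, and the dry residue volume.
Values follow the standard biomolecular compilations used for neutron
contrast calculations (Jacrot-type tables). Users may override the
table with their own CSV via :func:`surfprot.sld.load_residue_table`.
"""

from __future__ import annotations

# Coherent scattering lengths of hydrogen isotopes (fm)
B_H = -3.7406
B_D = 6.671
#: gain per H -> D substitution (fm)
B_EXCHANGE = B_D - B_H

# Pure-water scattering length densities (A^-2).
# Documented defaults; overridable wherever they are consumed.
SLD_H2O = -0.56e-6
SLD_D2O = 6.39e-6

# Avogadro's number
N_A = 6.02214076e23

# Boltzmann constant (J/K) and elementary charge (C), for Bjerrum length
K_B = 1.380649e-23
E_CHARGE = 1.602176634e-19
EPS0 = 8.8541878128e-12

#: per-residue (b_protonated [fm], n_exchangeable_H, volume [A^3])
RESIDUE_TABLE: dict[str, tuple[float, int, float]] = {
    "G": (17.28, 1, 66.4),
    "A": (16.45, 1, 91.5),
    "V": (14.79, 1, 141.7),
    "L": (13.96, 1, 167.9),
    "I": (13.96, 1, 168.8),
    "F": (41.39, 1, 203.4),
    "Y": (47.19, 2, 203.6),
    "W": (60.35, 2, 237.6),
    "D": (38.45, 1, 113.6),
    "E": (37.62, 1, 140.6),
    "S": (22.25, 2, 99.1),
    "T": (21.42, 2, 122.1),
    "N": (34.56, 3, 135.2),
    "Q": (33.73, 3, 161.1),
    "K": (15.86, 4, 176.2),
    "R": (34.66, 6, 180.8),
    "H": (49.59, 2, 167.3),
    "M": (17.64, 1, 170.8),
    "C": (19.30, 2, 105.6),
    "P": (22.27, 0, 129.3),
    # terminal water of the peptide-bond condensation convention: a chain
    # of n residues plus one water reconstitutes the intact molecule
    "HOH": (-1.679 * 10, 2, 30.0),
}
# note: HOH b = 2*B_H + 5.803 (O) = -1.678 e-12 cm = -16.78 fm
RESIDUE_TABLE["HOH"] = (2 * B_H + 5.803, 2, 30.0)

#: default fraction of labile hydrogens that actually exchange with solvent
DEFAULT_EXCHANGE_FRACTION = 0.90

#: molecular volume of one SDS molecule (whole molecule, A^3)
V_SDS = 412.0
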