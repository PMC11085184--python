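"""Physical constants used throughout the package.

Values are CODATA at the precision the characteristic-angle tables require.
Energies are carried in eV, lengths in nm unless a suffix says otherwise.
"""

#: Planck constant times speed of light, eV·nm.
HC_EV_NM = 1239.842

#: Electron rest energy, eV.
ELECTRON_REST_ENERGY_EV = 511_000.0

#: Bohr radius, nm.
BOHR_RADIUS_NM = 0.0529

#: Avogadro constant, 1/mol.
AVOGADRO = 6.022_140_76e23

#: nm per cm (for density conversions).
NM_PER_CM = 1.0e7
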