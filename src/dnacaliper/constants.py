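"""Physical constants and field-standard polymer defaults.

All lengths are in nm, forces in pN, energies in pN*nm, times in s.
Every value here can be overridden through the run configuration; these are
the defaults used by the presets and the simulator.
"""

#: Thermal energy at 23 degC (296 K), pN*nm.
KBT: float = 4.114

#: dsDNA persistence length, nm.
DS_PERSISTENCE_NM: float = 50.0
#: dsDNA helical rise, nm per base pair.
DS_RISE_NM_PER_BP: float = 0.34

#: ssDNA persistence length, nm.
SS_PERSISTENCE_NM: float = 1.0
#: ssDNA contour length, nm per nucleotide.
SS_RISE_NM_PER_NT: float = 0.59

#: Force plateau of dsDNA overstretching, pN (used only for tether QC).
OVERSTRETCH_PLATEAU_PN: float = 65.0
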