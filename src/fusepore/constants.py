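"""Physical constants and unit conventions.

All conductances are in pS, lengths in nm, times in ms unless a function
says otherwise.  Energies are in units of kT at 298 K.
"""

#: kT at 298 K expressed in pN*nm (1.380649e-23 J/K * 298 K = 4.114e-21 J).
KT_PN_NM = 4.114

#: Default solution conductivity, S/m.  Derived by solving the cylindrical
#: pore conductance model jointly for the two published correspondences
#: (200 pS <-> 0.76 nm and 1 nS <-> 1.70 nm with a 15 nm pore length),
#: which agree on sigma = 1.65 S/m to three figures.
DEFAULT_CONDUCTIVITY_S_PER_M = 1.65

#: Default pore (membrane-spanning cylinder) length, nm.
DEFAULT_PORE_LENGTH_NM = 15.0
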