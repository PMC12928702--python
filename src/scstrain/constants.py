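"""Physical constants and shared defaults (molecular units: nm, kcal/mol, e)."""

#: Boltzmann constant in kcal mol^-1 K^-1
KB_KCAL = 0.0019872041

#: Simulation temperature (K) used throughout unless overridden
DEFAULT_TEMPERATURE = 310.0

#: Bilayer bending modulus, 20 kBT expressed in kcal/mol
KAPPA_KCAL = 11.85

#: Vacuum permittivity (F m^-1)
EPS0_SI = 8.8541878128e-12

#: Boltzmann constant (J K^-1)
KB_SI = 1.380649e-23

#: Elementary charge (C)
E_CHARGE = 1.602176634e-19

#: Dielectric probe radius (nm)
PROBE_RADIUS_NM = 0.2

#: Reference bilayer thickness (nm)
D0_NM = 4.05

#: Surface-grid resolution (nm)
GRID_RESOLUTION_NM = 0.5

#: Radius of the protein-centred analysis mask (nm)
MASK_RADIUS_NM = 20.0

#: Effective membrane area used to normalise deformation energies (nm^2)
NORMALIZATION_AREA_NM2 = 1000.0

#: Mean distance between two uniform points in the unit square,
#: (2 + sqrt(2) + 5*asinh(1)) / 15
UNIT_SQUARE_MEAN_DISTANCE = 0.5214054331647207
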