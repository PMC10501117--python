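"""Parse a small reaction network, integrate it, and check a closed form.

The network below is the classic Fenton couple plus first-order organic
hydroperoxide homolysis.  ROOH decays with half-life ln2/k = 462 s, so
about 59% has decomposed by the end of the 600 s reaction stage.
"""

import numpy as np

from opkin import parse_network, run_assay_protocol

DOC = """
network demo
species:
  Fe2+  charge=2  init=1e-6
  Fe3+  charge=3
  H2O2  init=1e-6
  ROOH  init=1e-6
  OH
  OH-   charge=-1
  RO
reactions:
  fenton: Fe2+ + H2O2 -> Fe3+ + OH + OH- : k = 55 ; channel = OH ; source = lit
  hom:    ROOH -> OH + RO : k = 0.0015 ; channel = OH ; source = lit
"""

net = parse_network(DOC)
traj = run_assay_protocol(net)

rooh_600 = traj.conc_at("ROOH", 600.0)
print(f"ROOH remaining at 600 s : {rooh_600 * 1e6:.4f} uM")
print(f"closed form exp(-0.9)   : {np.exp(-0.9):.4f} uM")
print(f"cumulative homolysis extent: {traj.extent_of('hom')[-1] * 1e9:.2f} nmol/L")
# The simulated survival fraction matches the analytic exponential; the
# extent is the time-integrated homolysis flux used later for attribution.
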