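"""Shared model-spec texts and synthetic-sample specs for the tests."""

from mscipost.simulate import TowerSpec

FIG1_TEXT = """
# two species, one BDI event between sisters A and B
tree ((A,B)R;)
bdi X=A@0.00125 Y=B@0.00125
tau R=0.005
theta A=0.01 B=0.01 X=0.005 Y=0.02 R=0.01
phi X=0.7 Y=0.2
"""

# five species, three sister BDI events (A-B, D-E, S-U)
FIG5A_TEXT = """
tree (((A,B)S,(D,E)U)T,C)R;
bdi X1=A@0.001 Y1=B@0.001
bdi X2=D@0.001 Y2=E@0.001
bdi X3=S@0.003 Y3=U@0.003
tau R=0.006 T=0.004 S=0.002 U=0.002
theta A=.01 B=.01 C=.01 D=.01 E=.01 S=.01 U=.01 T=.01 R=.01 X1=.01 Y1=.01 X2=.01 Y2=.01 X3=.01 Y3=.01
phi X1=.1 Y1=.1 X2=.1 Y2=.1 X3=.1 Y3=.1
"""

# five species, two sister BDI events (D-E, S-U) and one nonsister (A-B)
FIG5B_TEXT = """
tree (((A,C)S,(D,E)U)T,B)R;
bdi X1=A@0.0005 Y1=B@0.0005
bdi X2=D@0.001 Y2=E@0.001
bdi X3=S@0.003 Y3=U@0.003
tau R=0.006 T=0.004 S=0.002 U=0.002
theta A=.01 B=.01 C=.01 D=.01 E=.01 S=.01 U=.01 T=.01 R=.01 X1=.01 Y1=.01 X2=.01 Y2=.01 X3=.01 Y3=.01
phi X1=.1 Y1=.1 X2=.1 Y2=.1 X3=.1 Y3=.1
"""

# two species, stacked double-BDI (lower X-Y under upper Z-W)
FIG6A_TEXT = """
tree ((A,B)R;)
bdi X=A@0.00125 Y=B@0.00125
bdi Z=A@0.0025 W=B@0.0025
tau R=0.005
theta A=0.005 B=0.02 X=0.005 Y=0.02 Z=0.005 W=0.02 R=0.005
phi X=0.1 Y=0.2 Z=0.2 W=0.3
"""

# three species, two nonsister BDI events -> four unidentifiable models.
# Synthetic rendering of that configuration: both events touch branch A.
S3_TEXT = """
tree ((B,C)S,A)R;
bdi X=A@0.001 Y=B@0.001
bdi Z=A@0.002 W=C@0.002
tau R=0.006 S=0.004
theta A=.01 B=.01 C=.01 S=.01 R=.01 X=.01 Y=.01 Z=.01 W=.01
phi X=.1 Y=.1 Z=.1 W=.1
"""

# four species, two unidirectional introgression events (network N1 as an
# MSci model): 11 branches, 5 node times, 2 introgression probabilities
FIG11D_TEXT = """
tree (((A,B)S,C)T,D)R;
udi H1=B@0.001 G1=A@0.001
udi H2=S@0.003 G2=C@0.003
tau R=0.006 T=0.004 S=0.002
theta A=.01 B=.01 C=.01 D=.01 S=.01 T=.01 R=.01 H1=.01 G1=.01 H2=.01 G2=.01
phi H1=.3 H2=.2
"""

PLAIN_TREE_TEXT = """
tree ((A,B)R;)
tau R=0.005
theta A=0.01 B=0.01 R=0.01
"""


def well_separated_2tower_spec(n=10_000, seed=0):
    """Twin towers far apart relative to their spread: phi means 0.7/0.2
    at high concentration, theta marginals tight around 0.01 and 0.02."""
    return TowerSpec(
        phi_params={"phi_X": (70.0, 30.0), "phi_Y": (20.0, 80.0)},
        theta_params={"theta_X": (100.0, 10000.0), "theta_Y": (100.0, 5000.0)},
        weights=(0.5, 0.5),
        stay_prob=0.995,
        n=n,
        seed=seed,
    )
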