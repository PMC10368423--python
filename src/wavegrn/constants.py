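"""Package-wide axis and species conventions.

Anterior-posterior (AP) convention: index 0 = anterior, increasing toward
posterior ("posterior to the right" in all plots and kymographs). Every
module that deals with positions along the embryo axis uses this convention;
do not flip axes locally.
"""

#: Index 0 of any AP-indexed array is the anterior end.
ANTERIOR_INDEX = 0

#: Species order used in simulation output arrays.
SPECIES = ("G1", "G2", "G3", "D1", "D2", "D3", "S1", "S2", "S3", "RD", "RS")

#: Image axis order for movie stacks.
MOVIE_AXES = ("t", "z", "y", "x")
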