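"""Published reference values for the house-mouse urinary proteoform family.

``MUP_DETECTION_SURVEY`` lists the urinary MUP proteoforms detected in a
survey of 36 wild-derived male house mice (UniProt accession, *Mup* gene
locus, percent of individuals in which the proteoform was identified).
It drives the frequency-classification worked example and anchors the
synthetic generator's default detection-probability ladder.
"""

from __future__ import annotations

__all__ = ["MUP_DETECTION_SURVEY", "SURVEY_N_INDIVIDUALS"]

SURVEY_N_INDIVIDUALS = 36

#: (accession, gene locus, detection frequency in percent of individuals)
MUP_DETECTION_SURVEY: list[tuple[str, str, int]] = [
    ("B8JI96", "Mup14", 100),
    ("Q5FW60", "Mup20", 100),
    ("A2AV72", "Mup6", 70),
    ("A9R9V7", "Mup21", 59),
    ("P11590", "Mup4", 54),
    ("B5TE76", "Mup17", 50),
    ("A9C497", "Mup19", 48),
    ("A2CEL1", "Mup1", 44),
    ("P11589", "Mup2", 41),
    ("A9R9W0", "Mup15", 41),
    ("A2CEK6", "Mup13", 39),
    ("B5X0G2", "Mup17", 35),
    ("P11591", "Mup5", 30),
    ("A2ANT6", "Mup6", 9),
    ("Q3KQQ2", "Mup3", 7),
    ("Q80YX8", "Mup21", 7),
    ("P04939", "Mup3", 6),
    ("Q58EV3", "Mup1", 2),
    ("L7MUC7", "Mup7", 2),
]
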