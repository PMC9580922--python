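"""Published per-threshold HSD summary counts for the A. thaliana proteome.

Each row: (threshold label, candidate, true, space, incomplete,
capturing %, score) as printed in the reference threshold-sweep summary.
Used as data-driven expectations for the evaluation statistics.
"""

ATHALIANA_SWEEP = [
    ("60%_10aa", 8647, 8245, 1584, 402, 95, 37),
    ("60%_30aa", 9447, 8797, 1831, 650, 93, 25),
    ("60%_50aa", 9571, 8767, 1917, 804, 91, 20),
    ("60%_70aa", 9510, 8610, 1931, 900, 90, 17),
    ("60%_100aa", 9472, 8434, 1921, 1038, 89, 15),
    ("70%_10aa", 8440, 8161, 1525, 279, 96, 53),
    ("70%_30aa", 9566, 9066, 1772, 500, 94, 33),
    ("70%_50aa", 9912, 9248, 1873, 664, 93, 25),
    ("70%_70aa", 10030, 9254, 1896, 776, 92, 22),
    ("70%_100aa", 10125, 9188, 1898, 937, 90, 18),
    ("80%_10aa", 7970, 7787, 1427, 183, 97, 77),
    ("80%_30aa", 9316, 8952, 1699, 364, 96, 45),
    ("80%_50aa", 9841, 9327, 1803, 514, 94, 33),
    ("80%_70aa", 10095, 9458, 1840, 637, 93, 27),
    ("80%_100aa", 10337, 9519, 1852, 818, 92, 21),
    ("90%_10aa", 7404, 7294, 1371, 110, 98, 120),
    ("90%_30aa", 8878, 8599, 1629, 279, 96, 56),
    ("90%_50aa", 9502, 9080, 1728, 422, 95, 39),
    ("90%_70aa", 9845, 9294, 1768, 551, 94, 31),
    ("90%_100aa", 10174, 9448, 1786, 726, 92, 24),
]
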