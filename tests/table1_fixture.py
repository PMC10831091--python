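"""Published benchmark confusion counts and printed metrics for four FFPE
artifact-removal tools across eleven strata.

Each row: (tool, stratum, tp, tn, fp, fn, specificity, sensitivity,
precision, f1, accuracy) with metrics as printed at 3 decimals.  Every
row was re-derived from its own counts before freezing; they serve as
exact fixtures for the metric formulas, not as tool reimplementations.
"""

TABLE1 = [
    # MuTect FilterByOrientationBias
    ("MuTect filter", "All (public WES dataset)", 401, 11204, 16306, 13, 0.407, 0.969, 0.024, 0.047, 0.416),
    ("MuTect filter", "Fibrosarcoma", 43, 0, 41, 0, 0.000, 1.000, 0.512, 0.677, 0.512),
    ("MuTect filter", "Lung cancer", 138, 124, 917, 2, 0.119, 0.986, 0.131, 0.231, 0.222),
    ("MuTect filter", "Liver cancer", 7, 0, 97, 0, 0.000, 1.000, 0.067, 0.126, 0.067),
    ("MuTect filter", "Colon cancer", 17, 0, 53, 0, 0.000, 1.000, 0.243, 0.391, 0.243),
    ("MuTect filter", "Breast cancer", 196, 11080, 15198, 11, 0.422, 0.947, 0.013, 0.025, 0.426),
    ("MuTect filter", "G:C>T:A", 47, 0, 1062, 0, 0.000, 1.000, 0.042, 0.081, 0.042),
    ("MuTect filter", "C:G>T:A", 142, 11204, 11603, 13, 0.491, 0.916, 0.012, 0.024, 0.494),
    ("MuTect filter", "Low MAF variants", 4, 110, 1360, 0, 0.075, 1.000, 0.003, 0.006, 0.077),
    ("MuTect filter", "A549 cells (WES)", 739, 0, 51, 0, 0.000, 1.000, 0.935, 0.967, 0.935),
    ("MuTect filter", "A549 cells (Targeted panel seq)", 15, 0, 6, 0, 0.000, 1.000, 0.714, 0.833, 0.714),
    # FFPolish
    ("FFPolish", "All (public WES dataset)", 282, 25607, 1903, 132, 0.931, 0.681, 0.129, 0.217, 0.927),
    ("FFPolish", "Fibrosarcoma", 32, 33, 8, 11, 0.805, 0.744, 0.800, 0.771, 0.774),
    ("FFPolish", "Lung cancer", 104, 949, 92, 36, 0.912, 0.743, 0.531, 0.619, 0.892),
    ("FFPolish", "Liver cancer", 0, 87, 10, 7, 0.897, 0.000, 0.000, 0.000, 0.837),
    ("FFPolish", "Colon cancer", 13, 42, 11, 4, 0.792, 0.765, 0.542, 0.634, 0.786),
    ("FFPolish", "Breast cancer", 133, 24496, 1782, 74, 0.932, 0.643, 0.069, 0.125, 0.930),
    ("FFPolish", "G:C>T:A", 41, 1028, 34, 6, 0.968, 0.872, 0.547, 0.672, 0.964),
    ("FFPolish", "C:G>T:A", 120, 21012, 1795, 35, 0.921, 0.774, 0.063, 0.116, 0.920),
    ("FFPolish", "Low MAF variants", 0, 1453, 17, 4, 0.988, 0.000, 0.000, 0.000, 0.986),
    ("FFPolish", "A549 cells (WES)", 648, 47, 4, 91, 0.922, 0.877, 0.994, 0.932, 0.880),
    ("FFPolish", "A549 cells (Targeted panel seq)", 13, 6, 0, 2, 1.000, 0.867, 1.000, 0.929, 0.905),
    # SOBDetector
    ("SOBDetector", "All (public WES dataset)", 352, 19852, 7658, 62, 0.722, 0.850, 0.044, 0.084, 0.724),
    ("SOBDetector", "Fibrosarcoma", 38, 16, 25, 5, 0.390, 0.884, 0.603, 0.717, 0.643),
    ("SOBDetector", "Lung cancer", 125, 585, 456, 15, 0.562, 0.893, 0.215, 0.347, 0.601),
    ("SOBDetector", "Liver cancer", 2, 62, 35, 5, 0.639, 0.286, 0.054, 0.091, 0.615),
    ("SOBDetector", "Colon cancer", 15, 30, 23, 2, 0.566, 0.882, 0.395, 0.545, 0.643),
    ("SOBDetector", "Breast cancer", 172, 19159, 7119, 35, 0.729, 0.831, 0.024, 0.046, 0.730),
    ("SOBDetector", "G:C>T:A", 47, 848, 214, 0, 0.798, 1.000, 0.180, 0.305, 0.807),
    ("SOBDetector", "C:G>T:A", 143, 15745, 7062, 12, 0.690, 0.923, 0.020, 0.039, 0.692),
    ("SOBDetector", "Low MAF variants", 3, 768, 702, 1, 0.522, 0.750, 0.004, 0.008, 0.523),
    ("SOBDetector", "A549 cells (WES)", 698, 24, 27, 41, 0.471, 0.945, 0.963, 0.954, 0.914),
    ("SOBDetector", "A549 cells (Targeted panel seq)", 13, 5, 1, 2, 0.833, 0.867, 0.929, 0.897, 0.857),
    # the neural-network classifier
    ("neural classifier", "All (public WES dataset)", 293, 27408, 102, 121, 0.996, 0.708, 0.742, 0.724, 0.992),
    ("neural classifier", "Fibrosarcoma", 37, 35, 6, 6, 0.854, 0.860, 0.860, 0.860, 0.857),
    ("neural classifier", "Lung cancer", 110, 996, 45, 30, 0.957, 0.786, 0.710, 0.746, 0.936),
    ("neural classifier", "Liver cancer", 5, 91, 6, 2, 0.938, 0.714, 0.455, 0.556, 0.923),
    ("neural classifier", "Colon cancer", 16, 49, 4, 1, 0.925, 0.941, 0.800, 0.865, 0.929),
    ("neural classifier", "Breast cancer", 125, 26237, 41, 82, 0.998, 0.604, 0.753, 0.670, 0.995),
    ("neural classifier", "G:C>T:A", 38, 1047, 15, 9, 0.986, 0.809, 0.717, 0.760, 0.978),
    ("neural classifier", "C:G>T:A", 89, 22786, 21, 66, 0.999, 0.574, 0.809, 0.672, 0.996),
    ("neural classifier", "Low MAF variants", 1, 1462, 8, 3, 0.995, 0.250, 0.111, 0.154, 0.993),
    ("neural classifier", "A549 cells (WES)", 711, 33, 18, 28, 0.647, 0.962, 0.975, 0.969, 0.942),
    ("neural classifier", "A549 cells (Targeted panel seq)", 15, 6, 0, 0, 1.000, 1.000, 1.000, 1.000, 1.000),
]


def row(tool: str, stratum: str):
    for r in TABLE1:
        if r[0] == tool and r[1] == stratum:
            return r
    raise KeyError((tool, stratum))
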