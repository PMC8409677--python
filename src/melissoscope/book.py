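"""Per-taxon descriptor statistics for the seven honey pollen taxa.

This module is the single source of the published per-taxon, per-modality
descriptor statistics (mean, SD) used to parameterize the synthetic phantom
generator and the feature-table sampler.  Seven taxa commonly dominating
Czech honeys are covered (Asteraceae, Pyrus/Prunus, Robinia, Tilia,
Brassica, Salix, Phacelia) under three transmitted-light modalities:
bright field (BF), dark field (DF) and phase contrast (Ph).

The 30 canonical descriptors comprise 13 two-dimensional morphological
measures, 2 equivalent-volume measures, 12 colour measures and 3
extended-depth-of-focus (EDF) measures.  ``density_variation`` has no
published marginal statistics; its book entry is derived by the delta
method from the intensity statistics (see :func:`_density_variation_sd`).
"""

from __future__ import annotations

import math
from typing import Dict, Tuple

TAXA = (
    "Asteraceae",
    "Pyrus/Prunus",
    "Robinia",
    "Tilia",
    "Brassica",
    "Salix",
    "Phacelia",
)

MODALITIES = ("BF", "DF", "Ph")

#: exine sculpture class per taxon (taxon-diagnostic pollen wall texture)
EXINE_CLASS = {
    "Asteraceae": "echinate",
    "Pyrus/Prunus": "striate",
    "Robinia": "psilate",
    "Tilia": "reticulate",
    "Brassica": "reticulate",
    "Salix": "reticulate",
    "Phacelia": "micro_reticulate",
}

#: canonical descriptor column order of a feature table
DESCRIPTORS = (
    # 13 morphological 2D
    "area",
    "eq_diameter",
    "perimeter",
    "mean_chord",
    "length",
    "width",
    "min_feret",
    "max_feret90",
    "circularity",
    "elongation",
    "shape_factor",
    "convexity",
    "roughness",
    # 2 volumetric 3D
    "volume_eq_sphere",
    "volume_eq_cylinder",
    # 12 colour
    "mean_intensity",
    "intensity_variation",
    "mean_red",
    "mean_green",
    "mean_blue",
    "hue_typical",
    "hue_variation",
    "mean_saturation",
    "mean_brightness",
    "bright_variation",
    "mean_density",
    "density_variation",
    # 3 EDF
    "edf_surface",
    "edf_roughness",
    "mean_edf_z",
)

#: physical unit of each descriptor (dimensionless entries are "1")
UNITS = {
    "area": "um^2",
    "eq_diameter": "um",
    "perimeter": "um",
    "mean_chord": "um",
    "length": "um",
    "width": "um",
    "min_feret": "um",
    "max_feret90": "um",
    "circularity": "1",
    "elongation": "1",
    "shape_factor": "1",
    "convexity": "1",
    "roughness": "1",
    "volume_eq_sphere": "um^3",
    "volume_eq_cylinder": "um^3",
    "mean_intensity": "8bit",
    "intensity_variation": "8bit",
    "mean_red": "8bit",
    "mean_green": "8bit",
    "mean_blue": "8bit",
    "hue_typical": "deg",
    "hue_variation": "deg",
    "mean_saturation": "%",
    "mean_brightness": "%",
    "bright_variation": "%",
    "mean_density": "OD",
    "density_variation": "OD",
    "edf_surface": "um^2",
    "edf_roughness": "1",
    "mean_edf_z": "um",
}

#: descriptors that are physically positive (truncated at > 0 when sampled)
SIZE_LIKE = frozenset(
    d for d in DESCRIPTORS if UNITS[d] in ("um", "um^2", "um^3")
) | {"elongation", "edf_roughness"}

# ---------------------------------------------------------------------------
# Published marginal statistics, one block per descriptor.
# Each row: taxon -> ((BF mean, BF sd), (DF mean, DF sd), (Ph mean, Ph sd)).
# ---------------------------------------------------------------------------

_T = Dict[str, Tuple[Tuple[float, float], ...]]

_LENGTH: _T = {
    "Asteraceae": ((38.14, 5.28), (41.75, 0.23), (62.12, 5.63)),
    "Pyrus/Prunus": ((33.34, 6.6), (35.49, 6.36), (35.37, 6.2)),
    "Robinia": ((26.67, 3.67), (26.3, 2.27), (26.66, 2.98)),
    "Tilia": ((26.5, 2.68), (27.71, 3.84), (26.98, 2.72)),
    "Brassica": ((25.36, 2.61), (25.1, 2.65), (25.12, 2.29)),
    "Salix": ((21.58, 2.98), (21.54, 2.37), (20.69, 2.36)),
    "Phacelia": ((23.59, 3.98), (24.6, 5.0), (24.69, 4.6)),
}

_CIRCULARITY: _T = {
    "Asteraceae": ((0.85, 0.02), (0.93, 0.01), (0.56, 0.05)),
    "Pyrus/Prunus": ((0.85, 0.09), (0.84, 0.09), (0.87, 0.08)),
    "Robinia": ((0.91, 0.07), (0.97, 0.02), (0.95, 0.04)),
    "Tilia": ((0.92, 0.08), (0.97, 0.02), (0.97, 0.02)),
    "Brassica": ((0.93, 0.05), (0.97, 0.03), (0.93, 0.06)),
    "Salix": ((0.91, 0.05), (0.95, 0.04), (0.95, 0.04)),
    "Phacelia": ((0.81, 0.07), (0.82, 0.06), (0.85, 0.07)),
}

_ELONGATION: _T = {
    "Asteraceae": ((1.12, 0.05), (1.1, 0.01), (1.09, 0.01)),
    "Pyrus/Prunus": ((1.22, 0.17), (1.24, 0.14), (1.26, 0.16)),
    "Robinia": ((1.11, 0.08), (1.14, 0.14), (1.11, 0.04)),
    "Tilia": ((1.18, 0.26), (1.12, 0.12), (1.1, 0.06)),
    "Brassica": ((1.17, 0.13), (1.16, 0.13), (1.15, 0.12)),
    "Salix": ((1.17, 0.13), (1.2, 0.14), (1.22, 0.14)),
    "Phacelia": ((1.82, 0.38), (2.0, 0.3), (1.81, 0.36)),
}

_SHAPE_FACTOR: _T = {
    "Asteraceae": ((0.93, 0.01), (0.94, 0.01), (0.91, 0.01)),
    "Pyrus/Prunus": ((0.92, 0.06), (0.87, 0.08), (0.89, 0.07)),
    "Robinia": ((0.96, 0.03), (0.98, 0.02), (0.97, 0.01)),
    "Tilia": ((0.96, 0.05), (0.98, 0.02), (0.98, 0.01)),
    "Brassica": ((0.97, 0.02), (0.98, 0.02), (0.97, 0.02)),
    "Salix": ((0.96, 0.02), (0.96, 0.03), (0.96, 0.02)),
    "Phacelia": ((0.85, 0.07), (0.83, 0.06), (0.86, 0.07)),
}

_CONVEXITY: _T = {
    "Asteraceae": ((0.96, 0.0), (0.97, 0.0), (0.94, 0.01)),
    "Pyrus/Prunus": ((0.97, 0.02), (0.96, 0.03), (0.97, 0.03)),
    "Robinia": ((0.98, 0.01), (0.99, 0.0), (0.98, 0.01)),
    "Tilia": ((0.98, 0.01), (0.99, 0.0), (0.99, 0.0)),
    "Brassica": ((0.98, 0.01), (0.99, 0.0), (0.98, 0.01)),
    "Salix": ((0.98, 0.01), (0.99, 0.01), (0.99, 0.01)),
    "Phacelia": ((0.98, 0.01), (0.99, 0.01), (0.99, 0.01)),
}

_AREA: _T = {
    "Asteraceae": ((1010.36, 298.59), (1175.94, 29.51), (1144.48, 16.93)),
    "Pyrus/Prunus": ((680.57, 218.79), (743.27, 213.18), (745.81, 214.2)),
    "Robinia": ((490.11, 124.4), (478.6, 69.08), (500.62, 109.91)),
    "Tilia": ((478.12, 88.57), (532.52, 141.79), (507.08, 109.22)),
    "Brassica": ((424.08, 61.33), (421.49, 66.71), (421.92, 52.91)),
    "Salix": ((304.8, 85.71), (299.44, 61.7), (272.05, 59.54)),
    "Phacelia": ((287.8, 73.49), (285.17, 84.78), (287.77, 77.94)),
}

_EQ_DIAMETER: _T = {
    "Asteraceae": ((35.37, 5.95), (38.69, 0.49), (38.17, 0.28)),
    "Pyrus/Prunus": ((29.07, 4.61), (30.46, 4.34), (30.51, 4.33)),
    "Robinia": ((24.75, 3.36), (24.63, 1.72), (25.11, 2.66)),
    "Tilia": ((24.57, 2.24), (25.82, 3.37), (25.27, 2.61)),
    "Brassica": ((23.18, 1.67), (23.1, 1.8), (23.13, 1.45)),
    "Salix": ((19.53, 2.57), (19.42, 2.05), (18.5, 2.05)),
    "Phacelia": ((18.97, 2.54), (18.83, 2.9), (18.96, 2.6)),
}

_PERIMETER: _T = {
    "Asteraceae": ((122.37, 21.5), (127.67, 1.7), (163.77, 9.37)),
    "Pyrus/Prunus": ((100.42, 17.78), (105.98, 17.85), (104.68, 17.26)),
    "Robinia": ((81.84, 11.02), (78.9, 5.59), (80.56, 8.74)),
    "Tilia": ((81.97, 8.37), (82.82, 10.85), (83.14, 8.52)),
    "Brassica": ((76.44, 6.15), (74.27, 6.09), (76.34, 5.68)),
    "Salix": ((64.94, 9.16), (63.03, 6.77), (60.25, 7.07)),
    "Phacelia": ((67.19, 9.75), (65.82, 10.06), (65.07, 9.37)),
}

_MEAN_CHORD: _T = {
    "Asteraceae": ((25.56, 4.15), (29.31, 0.44), (22.33, 0.87)),
    "Pyrus/Prunus": ((21.05, 3.39), (21.84, 3.03), (22.23, 3.08)),
    "Robinia": ((18.69, 2.81), (19.08, 1.35), (19.45, 2.03)),
    "Tilia": ((18.38, 1.81), (20.0, 2.64), (19.39, 2.18)),
    "Brassica": ((17.52, 1.29), (17.84, 1.37), (17.49, 1.19)),
    "Salix": ((14.63, 1.92), (14.84, 1.62), (14.13, 1.53)),
    "Phacelia": ((13.36, 1.8), (13.39, 2.19), (13.73, 1.94)),
}

_WIDTH: _T = {
    "Asteraceae": ((25.79, 5.07), (28.17, 0.77), (18.55, 1.4)),
    "Pyrus/Prunus": ((20.06, 3.27), (20.68, 3.19), (20.8, 3.14)),
    "Robinia": ((18.13, 2.93), (18.15, 1.49), (18.58, 2.03)),
    "Tilia": ((17.94, 1.95), (18.94, 2.56), (18.61, 2.04)),
    "Brassica": ((16.69, 1.34), (16.74, 1.45), (16.78, 1.25)),
    "Salix": ((13.94, 2.17), (13.8, 1.83), (13.04, 1.78)),
    "Phacelia": ((12.15, 2.34), (11.52, 2.37), (11.57, 1.88)),
}

_MIN_FERET: _T = {
    "Asteraceae": ((34.49, 6.12), (37.74, 0.28), (41.16, 0.39)),
    "Pyrus/Prunus": ((27.49, 4.34), (29.33, 4.77), (35.95, 6.11)),
    "Robinia": ((23.5, 3.9), (23.56, 1.8), (26.66, 2.98)),
    "Tilia": ((23.78, 2.29), (24.43, 3.39), (26.98, 2.72)),
    "Brassica": ((21.88, 1.71), (21.77, 1.83), (25.16, 2.28)),
    "Salix": ((18.46, 2.72), (18.13, 2.31), (20.71, 2.37)),
    "Phacelia": ((14.62, 2.34), (13.67, 2.55), (25.91, 4.54)),
}

_MAX_FERET90: _T = {
    "Asteraceae": ((35.96, 6.73), (39.99, 0.68), (37.96, 0.73)),
    "Pyrus/Prunus": ((28.26, 4.54), (30.21, 4.95), (28.82, 4.65)),
    "Robinia": ((23.98, 3.97), (24.21, 1.93), (24.24, 2.59)),
    "Tilia": ((24.65, 2.45), (25.15, 3.52), (24.44, 2.63)),
    "Brassica": ((22.28, 1.77), (22.3, 1.91), (21.98, 1.58)),
    "Salix": ((18.89, 2.88), (18.67, 2.46), (17.14, 2.28)),
    "Phacelia": ((14.8, 2.37), (13.86, 2.52), (14.5, 2.26)),
}

_VOLUME_EQ_SPHERE: _T = {
    "Asteraceae": ((25008.7, 9682.52), (30342.1, 1139.19), (29128.17, 647.67)),
    "Pyrus/Prunus": ((13860.17, 6818.67), (15704.87, 6842.05), (15786.02, 6905.51)),
    "Robinia": ((8363.28, 3106.08), (7936.04, 1786.02), (8573.61, 2932.24)),
    "Tilia": ((7963.97, 2257.87), (9483.78, 3879.13), (8733.98, 2949.11)),
    "Brassica": ((6620.79, 1449.94), (6569.32, 1620.67), (6557.9, 1233.99)),
    "Salix": ((4114.5, 1909.42), (3960.46, 1199.53), (3436.1, 1114.77)),
    "Phacelia": ((3764.48, 1382.61), (3743.42, 1633.23), (3772.12, 1547.15)),
}

_VOLUME_EQ_CYLINDER: _T = {
    "Asteraceae": ((16682.26, 6571.83), (20169.13, 877.25), (14960.25, 708.37)),
    "Pyrus/Prunus": ((9157.65, 4684.0), (10446.01, 4781.89), (10424.96, 4673.98)),
    "Robinia": ((5686.08, 2149.53), (5293.68, 1203.06), (5732.5, 1954.6)),
    "Tilia": ((5292.34, 1516.85), (6312.9, 2563.51), (5832.49, 1975.59)),
    "Brassica": ((4375.56, 943.83), (4346.71, 1052.6), (4353.41, 819.23)),
    "Salix": ((2707.37, 1270.08), (2601.91, 815.6), (2253.13, 755.84)),
    "Phacelia": ((2642.2, 1212.37), (2447.81, 1178.64), (2363.79, 996.4)),
}

_ROUGHNESS: _T = {
    "Asteraceae": ((0.95, 0.01), (0.99, 0.0), (0.78, 0.03)),
    "Pyrus/Prunus": ((0.97, 0.03), (0.98, 0.02), (0.99, 0.02)),
    "Robinia": ((0.98, 0.03), (1.0, 0.0), (1.0, 0.0)),
    "Tilia": ((0.97, 0.02), (1.0, 0.0), (0.99, 0.02)),
    "Brassica": ((0.98, 0.02), (0.99, 0.01), (0.98, 0.03)),
    "Salix": ((0.97, 0.02), (0.99, 0.01), (0.99, 0.01)),
    "Phacelia": ((0.97, 0.02), (1.0, 0.0), (0.99, 0.0)),
}

_EDF_SURFACE: _T = {
    "Asteraceae": ((1443.05, 613.87), (2655.49, 666.26), (2715.11, 345.82)),
    "Pyrus/Prunus": ((963.98, 319.21), (1157.8, 426.55), (2117.37, 2461.86)),
    "Robinia": ((746.91, 203.83), (730.03, 134.77), (4357.29, 3303.96)),
    "Tilia": ((667.22, 153.71), (1044.69, 419.97), (851.52, 265.39)),
    "Brassica": ((593.86, 114.86), (646.2, 165.0), (992.46, 1437.4)),
    "Salix": ((428.89, 130.13), (440.55, 128.02), (997.49, 1402.89)),
    "Phacelia": ((426.88, 122.97), (415.03, 160.3), (2104.09, 2741.91)),
}

_EDF_ROUGHNESS: _T = {
    "Asteraceae": ((1.38, 0.32), (2.26, 0.55), (2.37, 0.29)),
    "Pyrus/Prunus": ((1.42, 0.15), (1.55, 0.3), (3.32, 4.67)),
    "Robinia": ((1.52, 0.16), (1.52, 0.18), (8.59, 6.22)),
    "Tilia": ((1.39, 0.13), (1.92, 0.38), (1.67, 0.31)),
    "Brassica": ((1.4, 0.15), (1.53, 0.29), (2.36, 3.45)),
    "Salix": ((1.41, 0.16), (1.47, 0.29), (3.89, 5.47)),
    "Phacelia": ((1.48, 0.22), (1.43, 0.22), (7.32, 8.19)),
}

_MEAN_EDF_Z: _T = {
    "Asteraceae": ((5.27, 2.78), (9.81, 2.61), (20.08, 2.34)),
    "Pyrus/Prunus": ((11.07, 2.53), (11.68, 3.77), (10.27, 4.17)),
    "Robinia": ((10.46, 2.45), (9.01, 2.4), (15.17, 5.81)),
    "Tilia": ((6.75, 2.3), (13.22, 3.26), (10.63, 2.06)),
    "Brassica": ((10.78, 3.02), (12.42, 4.09), (12.12, 6.1)),
    "Salix": ((10.18, 2.81), (11.76, 4.64), (13.0, 5.37)),
    "Phacelia": ((10.36, 2.14), (9.73, 2.74), (13.26, 3.78)),
}

_MEAN_BRIGHTNESS: _T = {
    "Asteraceae": ((45.45, 2.3), (54.23, 0.39), (38.02, 0.25)),
    "Pyrus/Prunus": ((42.68, 5.65), (52.48, 4.74), (43.37, 4.12)),
    "Robinia": ((35.33, 1.37), (55.11, 3.43), (49.72, 2.74)),
    "Tilia": ((44.13, 3.09), (47.11, 4.09), (41.94, 2.89)),
    "Brassica": ((38.14, 4.48), (50.67, 3.8), (37.15, 2.09)),
    "Salix": ((40.37, 5.83), (53.16, 4.42), (43.18, 5.3)),
    "Phacelia": ((36.31, 1.35), (55.68, 2.93), (50.39, 2.4)),
}

_INTENSITY_VARIATION: _T = {
    "Asteraceae": ((12.31, 0.25), (23.8, 0.58), (10.2, 0.34)),
    "Pyrus/Prunus": ((10.41, 2.11), (16.6, 3.59), (10.75, 1.43)),
    "Robinia": ((8.16, 1.46), (18.57, 3.37), (13.51, 3.24)),
    "Tilia": ((9.9, 1.47), (23.51, 4.39), (8.91, 1.03)),
    "Brassica": ((8.93, 1.66), (17.78, 4.13), (8.63, 1.32)),
    "Salix": ((9.95, 4.46), (17.21, 4.26), (9.51, 1.84)),
    "Phacelia": ((7.36, 1.47), (13.87, 3.1), (11.14, 1.82)),
}

_BRIGHT_VARIATION: _T = {
    "Asteraceae": ((4.83, 0.1), (9.33, 0.23), (4.0, 0.14)),
    "Pyrus/Prunus": ((4.08, 0.83), (6.51, 1.41), (4.22, 0.56)),
    "Robinia": ((3.2, 0.57), (7.28, 1.32), (5.3, 1.27)),
    "Tilia": ((3.88, 0.57), (9.22, 1.72), (3.49, 0.41)),
    "Brassica": ((3.5, 0.65), (6.97, 1.62), (3.38, 0.52)),
    "Salix": ((3.9, 1.75), (6.75, 1.67), (3.73, 0.72)),
    "Phacelia": ((2.89, 0.57), (5.44, 1.21), (4.37, 0.71)),
}

_HUE_TYPICAL: _T = {
    "Asteraceae": ((32.05, 0.17), (47.04, 1.28), (33.74, 0.16)),
    "Pyrus/Prunus": ((38.79, 4.04), (52.69, 15.76), (39.52, 4.44)),
    "Robinia": ((43.9, 3.25), (73.54, 9.89), (41.09, 2.08)),
    "Tilia": ((33.4, 3.28), (37.64, 2.92), (46.48, 2.29)),
    "Brassica": ((34.82, 3.35), (43.76, 6.5), (38.22, 4.82)),
    "Salix": ((35.54, 4.19), (47.15, 8.88), (39.98, 5.94)),
    "Phacelia": ((40.0, 2.74), (95.22, 20.68), (42.69, 7.83)),
}

_MEAN_RED: _T = {
    "Asteraceae": ((137.52, 4.9), (147.75, 0.72), (110.71, 1.09)),
    "Pyrus/Prunus": ((123.66, 17.09), (141.14, 7.84), (122.65, 10.86)),
    "Robinia": ((99.88, 3.08), (141.26, 9.15), (139.67, 7.8)),
    "Tilia": ((134.81, 7.16), (135.01, 8.47), (116.44, 7.24)),
    "Brassica": ((116.12, 13.33), (141.64, 6.83), (107.31, 6.26)),
    "Salix": ((120.03, 16.11), (146.39, 9.56), (122.54, 13.71)),
    "Phacelia": ((101.42, 3.12), (139.1, 9.52), (139.44, 8.49)),
}

_MEAN_GREEN: _T = {
    "Asteraceae": ((122.58, 6.09), (148.61, 0.98), (102.45, 0.79)),
    "Pyrus/Prunus": ((115.26, 14.85), (142.29, 11.77), (117.74, 10.3)),
    "Robinia": ((95.94, 3.69), (147.49, 8.94), (133.33, 7.09)),
    "Tilia": ((118.4, 8.58), (129.21, 10.81), (117.27, 8.13)),
    "Brassica": ((103.63, 11.84), (140.79, 9.98), (101.93, 5.7)),
    "Salix": ((109.24, 14.94), (147.35, 11.98), (118.36, 14.91)),
    "Phacelia": ((98.23, 3.66), (148.15, 8.12), (135.94, 5.98)),
}

_MEAN_BLUE: _T = {
    "Asteraceae": ((87.58, 6.96), (118.48, 1.53), (77.73, 0.29)),
    "Pyrus/Prunus": ((87.57, 12.16), (118.02, 18.11), (91.39, 10.9)),
    "Robinia": ((74.48, 4.23), (132.81, 8.71), (107.37, 6.34)),
    "Tilia": ((84.42, 8.52), (96.15, 12.44), (87.12, 7.09)),
    "Brassica": ((72.05, 9.84), (105.18, 13.65), (74.95, 5.24)),
    "Salix": ((79.59, 14.85), (112.93, 15.08), (89.45, 12.69)),
    "Phacelia": ((78.12, 4.14), (138.66, 8.85), (110.09, 6.29)),
}

_MEAN_DENSITY: _T = {
    "Asteraceae": ((0.36, 0.02), (0.27, 0.0), (0.43, 0.0)),
    "Pyrus/Prunus": ((0.38, 0.06), (0.29, 0.05), (0.37, 0.04)),
    "Robinia": ((0.46, 0.02), (0.26, 0.03), (0.31, 0.02)),
    "Tilia": ((0.37, 0.03), (0.34, 0.04), (0.39, 0.03)),
    "Brassica": ((0.43, 0.06), (0.31, 0.04), (0.44, 0.03)),
    "Salix": ((0.41, 0.07), (0.28, 0.04), (0.37, 0.06)),
    "Phacelia": ((0.45, 0.02), (0.26, 0.02), (0.3, 0.02)),
}

_MEAN_INTENSITY: _T = {
    "Asteraceae": ((115.9, 5.87), (138.28, 0.98), (96.96, 0.64)),
    "Pyrus/Prunus": ((108.83, 14.4), (133.82, 12.08), (110.59, 10.52)),
    "Robinia": ((90.1, 3.49), (140.52, 8.74), (126.79, 6.98)),
    "Tilia": ((112.54, 7.88), (120.13, 10.42), (106.95, 7.37)),
    "Brassica": ((97.27, 11.41), (129.2, 9.7), (94.73, 5.33)),
    "Salix": ((102.95, 14.86), (135.56, 11.27), (110.12, 13.51)),
    "Phacelia": ((92.59, 3.45), (141.97, 7.46), (128.49, 6.11)),
}

_HUE_VARIATION: _T = {
    "Asteraceae": ((18.16, 2.55), (15.14, 1.3), (11.0, 1.09)),
    "Pyrus/Prunus": ((25.21, 7.56), (14.95, 8.96), (16.16, 5.32)),
    "Robinia": ((30.48, 7.48), (30.58, 4.17), (25.77, 5.19)),
    "Tilia": ((26.04, 9.76), (6.4, 1.75), (14.34, 2.93)),
    "Brassica": ((22.54, 9.88), (7.74, 3.57), (12.35, 4.04)),
    "Salix": ((21.86, 11.91), (10.45, 6.43), (11.96, 4.37)),
    "Phacelia": ((20.81, 8.03), (32.3, 7.59), (18.29, 6.14)),
}

_MEAN_SATURATION: _T = {
    "Asteraceae": ((62.09, 5.97), (37.0, 1.37), (50.06, 1.37)),
    "Pyrus/Prunus": ((49.94, 8.39), (32.2, 16.08), (44.43, 6.39)),
    "Robinia": ((44.73, 5.31), (16.51, 2.24), (38.59, 2.99)),
    "Tilia": ((64.62, 8.02), (51.94, 10.43), (47.38, 4.63)),
    "Brassica": ((66.54, 7.91), (48.07, 13.27), (53.23, 5.42)),
    "Salix": ((58.5, 12.57), (43.07, 14.37), (47.69, 6.83)),
    "Phacelia": ((39.53, 5.17), (16.57, 6.92), (36.04, 7.52)),
}

_TABLES = {
    "length": _LENGTH,
    "circularity": _CIRCULARITY,
    "elongation": _ELONGATION,
    "shape_factor": _SHAPE_FACTOR,
    "convexity": _CONVEXITY,
    "area": _AREA,
    "eq_diameter": _EQ_DIAMETER,
    "perimeter": _PERIMETER,
    "mean_chord": _MEAN_CHORD,
    "width": _WIDTH,
    "min_feret": _MIN_FERET,
    "max_feret90": _MAX_FERET90,
    "volume_eq_sphere": _VOLUME_EQ_SPHERE,
    "volume_eq_cylinder": _VOLUME_EQ_CYLINDER,
    "roughness": _ROUGHNESS,
    "edf_surface": _EDF_SURFACE,
    "edf_roughness": _EDF_ROUGHNESS,
    "mean_edf_z": _MEAN_EDF_Z,
    "mean_brightness": _MEAN_BRIGHTNESS,
    "intensity_variation": _INTENSITY_VARIATION,
    "bright_variation": _BRIGHT_VARIATION,
    "hue_typical": _HUE_TYPICAL,
    "mean_red": _MEAN_RED,
    "mean_green": _MEAN_GREEN,
    "mean_blue": _MEAN_BLUE,
    "mean_density": _MEAN_DENSITY,
    "mean_intensity": _MEAN_INTENSITY,
    "hue_variation": _HUE_VARIATION,
    "mean_saturation": _MEAN_SATURATION,
}


def _density_variation_entry(taxon: str, imod: int) -> Tuple[float, float]:
    """Delta-method stand-in for the unpublished optical-density spread.

    OD = -log10(I/255), so sd(OD) ~= sd(I) / (I_mean * ln 10).  The mean is
    taken from the published Mean Density.
    """
    mi, _ = _MEAN_INTENSITY[taxon][imod]
    iv, iv_sd = _INTENSITY_VARIATION[taxon][imod]
    md, _ = _MEAN_DENSITY[taxon][imod]
    sd_od = iv / (mi * math.log(10))
    # spread of the per-grain OD SD, propagated from the spread of IV
    sd_of_sd = iv_sd / (mi * math.log(10))
    return (sd_od, max(sd_of_sd, 0.1 * sd_od))


def stats_book() -> Dict[str, Dict[str, Dict[str, Tuple[float, float]]]]:
    """Return the full book: ``book[modality][taxon][descriptor] = (mean, sd)``.

    Covers all 30 canonical descriptors for the 7 taxa under BF, DF and Ph.
    """
    book: Dict[str, Dict[str, Dict[str, Tuple[float, float]]]] = {}
    for imod, mod in enumerate(MODALITIES):
        book[mod] = {}
        for taxon in TAXA:
            entry = {}
            for desc in DESCRIPTORS:
                if desc == "density_variation":
                    entry[desc] = _density_variation_entry(taxon, imod)
                else:
                    entry[desc] = _TABLES[desc][taxon][imod]
            book[mod][taxon] = entry
    return book


def descriptor_stat(modality: str, taxon: str, descriptor: str) -> Tuple[float, float]:
    """(mean, sd) for one descriptor of one taxon under one modality."""
    if descriptor == "density_variation":
        return _density_variation_entry(taxon, MODALITIES.index(modality))
    return _TABLES[descriptor][taxon][MODALITIES.index(modality)]
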