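"""Published reference tables for the vegetable-soybean core-collection study.

Per qualitative trait: the printed entire-collection (EC) and core-collection
(CC) level counts, the printed chi-squared homogeneity p-value, and the
printed per-collection diversity cells (S, normalised Shannon-Weaver H',
Nei). Quantitative entries carry the printed summary statistics and the
printed per-trait cluster counts used by the coverage percentages.
"""

# trait: (EC counts, CC counts, printed chi2 p,
#         (S, H', Nei) for EC, (S, H', Nei) for CC)
QUALITATIVE = {
    "seed_shape": ([107, 21, 58, 13], [15, 3, 9, 3], 0.91,
                   (4, 0.80, 0.61), (4, 0.84, 0.64)),
    "seed_coat_color": ([26, 69, 92, 1, 1], [4, 9, 15, 0, 0], 0.97,
                        (5, 0.65, 0.61), (3, 0.89, 0.59)),
    "hilum_color": ([13, 58, 102, 4], [2, 11, 11, 2], 0.28,
                    (4, 0.69, 0.55), (4, 0.81, 0.63)),
    "hypocotyl_coloration": ([131, 68], [18, 12], 0.68,
                             (2, 0.93, 0.45), (2, 0.97, 0.48)),
    "stem_color": ([106, 68, 8], [19, 11, 0], 0.49,
                   (3, 0.75, 0.52), (2, 0.95, 0.46)),
    "number_of_branches": ([58, 79, 62], [9, 10, 11], 0.77,
                           (3, 0.99, 0.66), (3, 1.00, 0.66)),
    "leaflet_size": ([81, 58, 11], [10, 11, 2], 0.64,
                     (3, 0.81, 0.55), (3, 0.84, 0.57)),
    "leaflet_shape": ([1, 37, 24, 46, 39], [1, 7, 1, 11, 4], 0.17,
                      (5, 0.87, 0.74), (5, 0.80, 0.67)),
    "leaf_color": ([46, 104], [6, 18], 0.75,
                   (2, 0.89, 0.43), (2, 0.81, 0.38)),
    "plant_type": ([142, 7], [22, 2], 0.80,
                   (2, 0.27, 0.09), (2, 0.41, 0.15)),
    "pubescence_density": ([4, 20, 33, 86, 56], [2, 6, 4, 7, 11], 0.10,
                           (5, 0.82, 0.70), (5, 0.92, 0.75)),
    "pubescence_color": ([102, 63, 32], [11, 11, 6], 0.46,
                         (3, 0.91, 0.60), (3, 0.97, 0.65)),
    "corolla_color": ([138, 34, 27], [20, 7, 3], 0.65,
                      (3, 0.75, 0.47), (3, 0.76, 0.49)),
    "pod_set_capacity": ([13, 54, 82], [1, 8, 15], 0.68,
                         (3, 0.83, 0.56), (3, 0.72, 0.50)),
}

# observed-vs-completed summaries: (n, mean, SD) pairs and printed p
OBSERVED_VS_IMPUTED_PLANT_HEIGHT = ((198, 37.09, 10.71), (200, 37.01, 10.69), 0.94)
OBSERVED_VS_IMPUTED_PLANT_TYPE = ([142, 7], [177, 23], 0.04)

# EC-vs-CC plant height: summaries, printed Levene p, printed Welch p
EC_VS_CC_PLANT_HEIGHT = ((198, 37.1, 10.7), (30, 45.2, 14.4), 0.007, 0.01)

# per-trait cluster counts (EC, CC) behind the printed coverage percentages
COVERAGE_K_QUANT = {
    "seed_length": (6, 6), "seed_width": (9, 9), "seed_thickness": (5, 5),
    "hundred_seed_weight": (12, 11), "plant_height": (11, 9),
    "leaflet_length": (3, 3), "leaflet_width": (6, 6), "pod_length": (10, 7),
    "pod_width": (5, 4), "stem_length_to_first_pod": (5, 4),
    "shelling_rate": (5, 4), "immature_seed_length": (6, 6),
    "immature_seed_width": (9, 8), "immature_seed_thickness": (6, 5),
    "hundred_immature_seed_weight": (6, 6),
}
COVERAGE_K_QUAL = {
    name: (vals[3][0], vals[4][0]) for name, vals in QUALITATIVE.items()
}
COVERAGE_PCT_PRINTED = {"quantitative": 90.38, "qualitative": 94.76,
                        "combined": 92.50}
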