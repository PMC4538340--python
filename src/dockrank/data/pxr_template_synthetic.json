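{
  "schema_version": 1,
  "name": "pxr_five_feature_template_synthetic",
  "comment": "Five-feature PXR agonist template: the feature-type signature (Hyd|Acc, Acc|Acc2|Don2, Hyd|Acc2, Hyd|Acc, ARO|Hyd, 8 excluded volumes) follows the published model; the coordinates, tolerances and radii are SYNTHETIC placeholders, not the unpublished geometry. The placeholder geometry is deliberately irregular: no non-identity feature permutation superposes onto the template within tolerance, so assignment ambiguity cannot occur. Non-canonical; for engine demonstration and testing only.",
  "features": [
    {"types": ["Acc", "Hyd"], "center": [7.85, 6.99, 0.13], "tolerance": 1.0},
    {"types": ["Acc", "Acc2", "Don2"], "center": [4.57, 0.56, 5.04], "tolerance": 1.0},
    {"types": ["Acc2", "Hyd"], "center": [5.27, 3.31, 1.07], "tolerance": 1.0},
    {"types": ["Acc", "Hyd"], "center": [0.74, 2.7, 8.31], "tolerance": 1.0},
    {"types": ["ARO", "Hyd"], "center": [7.95, 0.63, 1.24], "tolerance": 1.0}
  ],
  "excluded_volumes": [
    {"center": [11.5, 3.0, 3.0], "radius": 1.4},
    {"center": [2.0, 7.0, 3.0], "radius": 1.4},
    {"center": [8.5, 3.5, 7.5], "radius": 1.4},
    {"center": [1.0, -1.5, 2.0], "radius": 1.4},
    {"center": [5.0, 7.5, 6.5], "radius": 1.4},
    {"center": [-2.0, 3.0, 8.0], "radius": 1.4},
    {"center": [9.0, -2.5, 4.5], "radius": 1.4},
    {"center": [4.0, 3.0, -3.0], "radius": 1.4}
  ],
  "min_features_required": 5
}
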