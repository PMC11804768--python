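"""Published clinimetric reference values for a consumer balance board.

Reference numbers from a validation study of a four-corner-sensor
consumer balance board (index device) against a laboratory-grade force
platform (reference device): per-task SEM/MDC pairs from the test-retest
analysis and per-task device means with their absolute agreement from the
concurrent-validity analysis.  All values are printed to three decimals
in the source tables, so independently rounded quantities can disagree by
one unit in the last place.

Units: cm for displacement SDs and pathlength, cm/s for velocities,
cm^2 for the 95% prediction ellipse area.
"""

from __future__ import annotations

__all__ = ["SEM_MDC_ROWS", "DEVICE_MEAN_ROWS"]

# (stance, metric, task, device, sem, mdc); device: 'board' = index,
# 'plate' = reference.  Bipedal tasks: 1-EO eyes open, 2-EC/3-EC eyes
# closed; unipedal tasks: R/L leg, trials 1-3.
SEM_MDC_ROWS = [
    ("bipedal", "sd_ml", "1-EO", "board", 0.045, 0.125),
    ("bipedal", "sd_ml", "1-EO", "plate", 0.047, 0.130),
    ("bipedal", "sd_ml", "2-EC", "board", 0.029, 0.079),
    ("bipedal", "sd_ml", "2-EC", "plate", 0.026, 0.072),
    ("bipedal", "sd_ml", "3-EC", "board", 0.036, 0.099),
    ("bipedal", "sd_ml", "3-EC", "plate", 0.034, 0.093),
    ("bipedal", "sd_ap", "1-EO", "board", 0.105, 0.291),
    ("bipedal", "sd_ap", "1-EO", "plate", 0.083, 0.229),
    ("bipedal", "sd_ap", "2-EC", "board", 0.110, 0.306),
    ("bipedal", "sd_ap", "2-EC", "plate", 0.115, 0.319),
    ("bipedal", "sd_ap", "3-EC", "board", 0.073, 0.201),
    ("bipedal", "sd_ap", "3-EC", "plate", 0.076, 0.211),
    ("bipedal", "v_ml", "1-EO", "board", 0.059, 0.163),
    ("bipedal", "v_ml", "1-EO", "plate", 0.081, 0.226),
    ("bipedal", "v_ml", "2-EC", "board", 0.067, 0.185),
    ("bipedal", "v_ml", "2-EC", "plate", 0.068, 0.188),
    ("bipedal", "v_ml", "3-EC", "board", 0.069, 0.192),
    ("bipedal", "v_ml", "3-EC", "plate", 0.078, 0.217),
    ("bipedal", "v_ap", "1-EO", "board", 0.153, 0.425),
    ("bipedal", "v_ap", "1-EO", "plate", 0.237, 0.657),
    ("bipedal", "v_ap", "2-EC", "board", 0.232, 0.644),
    ("bipedal", "v_ap", "2-EC", "plate", 0.233, 0.645),
    ("bipedal", "v_ap", "3-EC", "board", 0.181, 0.503),
    ("bipedal", "v_ap", "3-EC", "plate", 0.191, 0.529),
    ("bipedal", "pathlength", "1-EO", "board", 3.303, 9.155),
    ("bipedal", "pathlength", "1-EO", "plate", 4.958, 13.744),
    ("bipedal", "pathlength", "2-EC", "board", 4.704, 13.039),
    ("bipedal", "pathlength", "2-EC", "plate", 4.745, 13.152),
    ("bipedal", "pathlength", "3-EC", "board", 3.874, 10.737),
    ("bipedal", "pathlength", "3-EC", "plate", 4.160, 11.532),
    ("bipedal", "pea95", "1-EO", "board", 0.431, 1.194),
    ("bipedal", "pea95", "1-EO", "plate", 0.439, 1.216),
    ("bipedal", "pea95", "2-EC", "board", 0.375, 1.040),
    ("bipedal", "pea95", "2-EC", "plate", 0.394, 1.093),
    ("bipedal", "pea95", "3-EC", "board", 0.385, 1.069),
    ("bipedal", "pea95", "3-EC", "plate", 0.417, 1.157),
    ("unipedal", "sd_ml", "R1", "board", 0.094, 0.259),
    ("unipedal", "sd_ml", "R1", "plate", 0.094, 0.261),
    ("unipedal", "sd_ml", "R2", "board", 0.089, 0.246),
    ("unipedal", "sd_ml", "R2", "plate", 0.091, 0.252),
    ("unipedal", "sd_ml", "R3", "board", 0.090, 0.248),
    ("unipedal", "sd_ml", "R3", "plate", 0.093, 0.258),
    ("unipedal", "sd_ml", "L1", "board", 0.083, 0.231),
    ("unipedal", "sd_ml", "L1", "plate", 0.083, 0.230),
    ("unipedal", "sd_ml", "L2", "board", 0.094, 0.260),
    ("unipedal", "sd_ml", "L2", "plate", 0.099, 0.275),
    ("unipedal", "sd_ml", "L3", "board", 0.065, 0.181),
    ("unipedal", "sd_ml", "L3", "plate", 0.069, 0.190),
    ("unipedal", "sd_ap", "R1", "board", 0.146, 0.406),
    ("unipedal", "sd_ap", "R1", "plate", 0.144, 0.399),
    ("unipedal", "sd_ap", "R2", "board", 0.144, 0.399),
    ("unipedal", "sd_ap", "R2", "plate", 0.150, 0.415),
    ("unipedal", "sd_ap", "R3", "board", 0.157, 0.435),
    ("unipedal", "sd_ap", "R3", "plate", 0.169, 0.469),
    ("unipedal", "sd_ap", "L1", "board", 0.107, 0.296),
    ("unipedal", "sd_ap", "L1", "plate", 0.107, 0.298),
    ("unipedal", "sd_ap", "L2", "board", 0.121, 0.335),
    ("unipedal", "sd_ap", "L2", "plate", 0.126, 0.349),
    ("unipedal", "sd_ap", "L3", "board", 0.128, 0.356),
    ("unipedal", "sd_ap", "L3", "plate", 0.138, 0.382),
    ("unipedal", "v_ml", "R1", "board", 0.586, 1.623),
    ("unipedal", "v_ml", "R1", "plate", 0.548, 1.518),
    ("unipedal", "v_ml", "R2", "board", 0.513, 1.423),
    ("unipedal", "v_ml", "R2", "plate", 0.476, 1.319),
    ("unipedal", "v_ml", "R3", "board", 0.420, 1.164),
    ("unipedal", "v_ml", "R3", "plate", 0.382, 1.059),
    ("unipedal", "v_ml", "L1", "board", 0.574, 1.592),
    ("unipedal", "v_ml", "L1", "plate", 0.557, 1.543),
    ("unipedal", "v_ml", "L2", "board", 0.647, 1.795),
    ("unipedal", "v_ml", "L2", "plate", 0.623, 1.727),
    ("unipedal", "v_ml", "L3", "board", 0.544, 1.508),
    ("unipedal", "v_ml", "L3", "plate", 0.528, 1.464),
    ("unipedal", "v_ap", "R1", "board", 0.573, 1.588),
    ("unipedal", "v_ap", "R1", "plate", 0.649, 1.800),
    ("unipedal", "v_ap", "R2", "board", 0.597, 1.655),
    ("unipedal", "v_ap", "R2", "plate", 0.595, 1.649),
    ("unipedal", "v_ap", "R3", "board", 0.381, 1.055),
    ("unipedal", "v_ap", "R3", "plate", 0.398, 1.103),
    ("unipedal", "v_ap", "L1", "board", 0.547, 1.516),
    ("unipedal", "v_ap", "L1", "plate", 0.549, 1.521),
    ("unipedal", "v_ap", "L2", "board", 0.566, 1.570),
    ("unipedal", "v_ap", "L2", "plate", 0.566, 1.569),
    ("unipedal", "v_ap", "L3", "board", 0.530, 1.470),
    ("unipedal", "v_ap", "L3", "plate", 0.562, 1.557),
    ("unipedal", "pathlength", "R1", "board", 12.514, 34.686),
    ("unipedal", "pathlength", "R1", "plate", 12.660, 35.092),
    ("unipedal", "pathlength", "R2", "board", 11.725, 32.500),
    ("unipedal", "pathlength", "R2", "plate", 11.227, 31.120),
    ("unipedal", "pathlength", "R3", "board", 8.247, 22.860),
    ("unipedal", "pathlength", "R3", "plate", 8.081, 22.398),
    ("unipedal", "pathlength", "L1", "board", 12.401, 34.374),
    ("unipedal", "pathlength", "L1", "plate", 12.191, 33.792),
    ("unipedal", "pathlength", "L2", "board", 13.155, 36.464),
    ("unipedal", "pathlength", "L2", "plate", 12.943, 35.876),
    ("unipedal", "pathlength", "L3", "board", 11.845, 32.833),
    ("unipedal", "pathlength", "L3", "plate", 11.995, 33.249),
    ("unipedal", "pea95", "R1", "board", 2.084, 5.776),
    ("unipedal", "pea95", "R1", "plate", 2.041, 5.656),
    ("unipedal", "pea95", "R2", "board", 2.218, 6.148),
    ("unipedal", "pea95", "R2", "plate", 2.341, 6.489),
    ("unipedal", "pea95", "R3", "board", 2.062, 5.716),
    ("unipedal", "pea95", "R3", "plate", 2.182, 6.049),
    ("unipedal", "pea95", "L1", "board", 1.664, 4.613),
    ("unipedal", "pea95", "L1", "plate", 1.720, 4.768),
    ("unipedal", "pea95", "L2", "board", 1.779, 4.930),
    ("unipedal", "pea95", "L2", "plate", 1.862, 5.162),
    ("unipedal", "pea95", "L3", "board", 1.551, 4.300),
    ("unipedal", "pea95", "L3", "plate", 1.647, 4.566),
]

# (stance, metric, task, index_mean, reference_mean, published_absolute_agreement)
# First measurement series; absolute agreement = reference - index.
DEVICE_MEAN_ROWS = [
    ("bipedal", "sd_ml", "1-EO", 0.182, 0.179, -0.003),
    ("bipedal", "sd_ml", "2-EC", 0.155, 0.145, -0.010),
    ("bipedal", "sd_ml", "3-EC", 0.165, 0.158, -0.006),
    ("bipedal", "sd_ap", "1-EO", 0.424, 0.437, 0.014),
    ("bipedal", "sd_ap", "2-EC", 0.420, 0.432, 0.012),
    ("bipedal", "sd_ap", "3-EC", 0.392, 0.405, 0.013),
    ("bipedal", "v_ml", "1-EO", 0.534, 0.425, -0.109),
    ("bipedal", "v_ml", "2-EC", 0.543, 0.416, -0.127),
    ("bipedal", "v_ml", "3-EC", 0.517, 0.396, -0.121),
    ("bipedal", "v_ap", "1-EO", 0.821, 0.800, -0.022),
    ("bipedal", "v_ap", "2-EC", 1.130, 1.118, -0.012),
    ("bipedal", "v_ap", "3-EC", 1.065, 1.056, -0.009),
    ("bipedal", "pathlength", "1-EO", 21.531, 19.746, -1.785),
    ("bipedal", "pathlength", "2-EC", 27.028, 25.421, -1.608),
    ("bipedal", "pathlength", "3-EC", 25.563, 24.006, -1.556),
    ("bipedal", "pea95", "1-EO", 1.353, 1.405, 0.052),
    ("bipedal", "pea95", "2-EC", 1.134, 1.178, 0.044),
    ("bipedal", "pea95", "3-EC", 1.164, 1.219, 0.055),
    ("unipedal", "sd_ml", "R1", 0.566, 0.572, 0.006),
    ("unipedal", "sd_ap", "R1", 0.692, 0.715, 0.023),
    ("unipedal", "v_ml", "R1", 3.792, 3.685, -0.107),
    ("unipedal", "v_ap", "R1", 3.157, 3.196, 0.039),
    ("unipedal", "pathlength", "R1", 81.018, 80.132, -0.886),
    ("unipedal", "pea95", "R1", 7.437, 7.788, 0.351),
]
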