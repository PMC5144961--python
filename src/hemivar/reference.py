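"""Published point estimates for the 80-line hemiclone lifespan/aging study design.

These are posterior means from the multi-response mixed-model analysis of the
full 32,000-fly chromosome-substitution experiment (40 X-lines + 40 A-lines,
two sexes, four batches).  They serve two purposes here:

* they parameterize the synthetic-data generator's default study conditions,
  so simulated data have the variance structure of the real experiment; and
* they are the inputs to the exact arithmetic identities among derived
  quantities (``V_A`` conversion, ``V_P`` sums, plug-in ``CV_A``).

Lifespan entries are in days (variances days²); aging entries are on the
β × 100 scale (per-day demographic rate of aging times 100).
"""

from __future__ import annotations

# trait -> chromosome type ('A' autosomes, 'X') -> sex ('F', 'M') -> component
TABLE1: dict[str, dict[str, dict[str, dict[str, float]]]] = {
    "lifespan": {
        "A": {
            "F": {"mean": 64.75, "V_L": 15.00, "V_V": 4.78, "V_R": 73.72,
                  "V_P": 93.49, "V_A": 30.00, "CV_A": 0.08},
            "M": {"mean": 50.03, "V_L": 17.36, "V_V": 4.82, "V_R": 89.92,
                  "V_P": 112.10, "V_A": 34.71, "CV_A": 0.12},
        },
        "X": {
            "F": {"mean": 67.80, "V_L": 2.28, "V_V": 5.96, "V_R": 60.95,
                  "V_P": 69.19, "V_A": 4.57, "CV_A": 0.03},
            "M": {"mean": 51.36, "V_L": 8.95, "V_V": 3.19, "V_R": 98.84,
                  "V_P": 110.98, "V_A": 8.95, "CV_A": 0.06},
        },
    },
    "aging": {
        "A": {
            "F": {"mean": 17.29, "V_L": 6.97, "V_R": 25.86,
                  "V_P": 32.83, "V_A": 13.94, "CV_A": 0.206},
            "M": {"mean": 12.41, "V_L": 3.07, "V_R": 6.66,
                  "V_P": 9.73, "V_A": 6.14, "CV_A": 0.196},
        },
        "X": {
            "F": {"mean": 14.77, "V_L": 1.01, "V_R": 12.55,
                  "V_P": 13.56, "V_A": 2.02, "CV_A": 0.085},
            "M": {"mean": 10.95, "V_L": 0.78, "V_R": 3.03,
                  "V_P": 3.81, "V_A": 0.78, "CV_A": 0.078},
        },
    },
}

#: intersexual additive genetic correlations (posterior means)
RMF: dict[str, dict[str, float]] = {
    "lifespan": {"A": 0.50, "X": 0.06},
    "aging": {"A": -0.12, "X": -0.42},
}

#: fraction of the genome attributable to the X chromosome, two metrics
X_FRACTION_EUCHROMATIN = 0.188
X_FRACTION_GENES = 0.156
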