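"""Frozen reference values for the default two-crystal configuration.

The coincidence-probability tables below are the published reference results
for 57.4 x 57.4 x 10 mm^3 LYSO crystals at separations 0, 2.5, 10 and 21 cm,
with the absorption probabilities of
``lutebg.photon_mc.reference_absorption_probabilities`` as input.  They are
quoted to 3 significant figures.
"""

DISTANCES = (0.0, 2.5, 10.0, 21.0)

# source crystal (C1): cascade energy shifting the beta continuum -> probability
REFERENCE_C1 = {
    0:   (1.60e-4, 8.33e-5, 1.76e-5, 4.70e-6),
    88:  (3.15e-2, 1.44e-2, 2.76e-3, 7.34e-4),
    202: (6.59e-4, 3.04e-4, 6.01e-5, 1.57e-5),
    290: (8.39e-2, 3.11e-2, 5.37e-3, 1.38e-3),
    307: (2.20e-4, 1.10e-4, 2.27e-5, 6.03e-6),
    395: (3.44e-2, 1.52e-2, 2.87e-3, 7.67e-4),
    509: (7.53e-4, 3.34e-4, 6.55e-5, 1.70e-5),
    597: (0.0, 0.0, 0.0, 0.0),
}

# detector crystal (C2): photopeak energy -> probability
REFERENCE_C2 = {
    0:   (0.0, 0.0, 0.0, 0.0),
    88:  (1.23e-3, 6.05e-4, 1.25e-4, 3.26e-5),
    202: (5.03e-2, 2.38e-2, 4.65e-3, 1.25e-3),
    290: (7.30e-5, 1.53e-5, 5.86e-7, 4.08e-8),
    307: (9.43e-2, 3.61e-2, 6.37e-3, 1.65e-3),
    395: (1.37e-4, 2.33e-5, 8.04e-7, 5.39e-8),
    509: (5.59e-3, 9.15e-4, 2.99e-5, 2.06e-6),
    597: (8.11e-6, 5.89e-7, 3.78e-9, 6.74e-11),
}

#: relative tolerance consistent with values printed to 3 significant figures
PRINTED_RTOL = 6e-3
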