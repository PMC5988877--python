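"""Published fetal-QRS detection benchmark on 12 labor recordings.

Per-recording (TP, FP, FN) counts with the percentages printed next to
them, for the ICA- and PCA-based extractions; used as worked-example
oracles for the detection statistics.
"""

# recording: ((TP, FP, FN), (Se, PPV, ACC, F1))
ICA_TABLE = {
    "real01": ((644, 2, 3), (99.54, 99.69, 99.23, 99.61)),
    "real02": ((663, 9, 5), (99.25, 98.66, 97.93, 98.96)),
    "real03": ((686, 14, 7), (98.99, 98.00, 97.03, 98.49)),
    "real04": ((643, 11, 19), (97.13, 98.32, 95.54, 97.72)),
    "real05": ((645, 5, 7), (98.93, 99.23, 98.17, 99.08)),
    "real06": ((676, 12, 15), (97.83, 98.26, 96.16, 98.04)),
    "real07": ((626, 6, 24), (96.31, 99.05, 95.43, 97.66)),
    "real08": ((651, 4, 3), (99.54, 99.39, 98.94, 99.47)),
    "real09": ((657, 5, 4), (99.39, 99.24, 98.65, 99.32)),
    "real10": ((635, 3, 24), (96.36, 99.53, 95.92, 97.92)),
    "real11": ((719, 10, 17), (97.69, 98.63, 96.38, 98.16)),
    "real12": ((688, 10, 15), (97.87, 98.57, 96.49, 98.22)),
}
ICA_TOTAL_COUNTS = (7933, 91, 143)
ICA_TOTAL_PCT = (98.23, 98.87, 97.13, 98.55)

PCA_TABLE = {
    "real01": ((644, 1, 2), (99.69, 99.84, 99.54, 99.77)),
    "real02": ((663, 14, 13), (98.08, 97.93, 96.09, 98.00)),
    "real03": ((686, 14, 9), (98.71, 98.00, 96.76, 98.35)),
    "real04": ((643, 12, 17), (97.42, 98.17, 95.68, 97.79)),
    "real05": ((645, 3, 8), (98.77, 99.54, 98.32, 99.15)),
    "real06": ((676, 9, 16), (97.69, 98.69, 96.43, 98.18)),
    "real07": ((626, 10, 17), (97.36, 98.43, 95.87, 97.89)),
    "real08": ((651, 2, 2), (99.69, 99.69, 99.39, 99.69)),
    "real09": ((657, 13, 6), (99.10, 98.06, 97.19, 98.57)),
    "real10": ((635, 6, 14), (97.84, 99.06, 96.95, 98.45)),
    "real11": ((719, 3, 21), (97.16, 99.58, 96.77, 98.36)),
    "real12": ((688, 5, 16), (97.73, 99.28, 97.04, 98.50)),
}
# the published PCA Total row percentages equal the mean of the
# per-recording percentages, not the pooled-count statistics
PCA_TOTAL_PCT = (98.27, 98.86, 97.17, 98.56)
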