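"""Reference particle-analysis rows for the printed-precision audit.

These are previously reported summary rows (rat sodium-iodate RPE flat
mounts; melanin / lipofuscin particle counts) used to audit the table
identity ``Average size = Total area / Count`` at the precision each value
was printed with.  Each row is (dose, day, count, total_area, printed
average size string).

Rows whose printed values do not satisfy the identity even at printed
precision (transcription or typesetting defects in the source tables) are
kept separately with the recomputed value, and are excluded from the audit.
"""

from __future__ import annotations

#: (table, dose, day, count, total_area, printed_average_size)
CONSISTENT_ROWS: list[tuple[str, str, int, float, float, str]] = [
    ("melanin_total", "LOW_40", 1, 11331, 28.355, "0.003"),
    ("melanin_total", "LOW_40", 1, 4837, 27.377, "0.006"),
    ("melanin_total", "LOW_40", 1, 5908, 29.601, "0.005"),
    ("melanin_total", "HIGH_60", 1, 3004, 38.165, "0.013"),
    ("melanin_total", "LOW_40", 7, 2189, 32.981, "0.015"),
    ("melanin_total", "LOW_40", 7, 5027, 30.979, "0.006"),
    ("melanin_total", "HIGH_60", 7, 8931, 26.479, "0.003"),
    ("melanin_total", "HIGH_60", 7, 11089, 29.17, "0.003"),
    ("melanin_total", "LOW_40", 30, 5997, 28.524, "0.005"),
    ("melanin_total", "LOW_40", 30, 11263, 7.327, "6.51E-04"),
    ("melanin_total", "LOW_40", 30, 10501, 9.992, "9.52E-04"),
    ("melanin_total", "LOW_40", 30, 10975, 12.0, "0.001"),
    ("melanin_total", "HIGH_60", 30, 4429, 24.807, "0.006"),
    ("melanin_total", "HIGH_60", 30, 3966, 26.011, "0.007"),
    ("melanin_total", "HIGH_60", 30, 5423, 24.652, "0.005"),
    ("melanin_total", "HIGH_60", 30, 11705, 22.066, "0.002"),
    ("melanin_mean", "LOW_40", 1, 829, 7.933, "0.01"),
    ("melanin_mean", "LOW_40", 7, 3435, 1.359, "3.96E-04"),
    ("lipofuscin_mean", "LOW_40", 1, 3049, 20.183, "0.007"),
    ("lipofuscin_mean", "LOW_40", 7, 5914, 16.148, "0.003"),
]

#: rows excluded from the audit: either the printed average size disagrees
#: with total_area / count by far more than printed-precision rounding, or
#: the row is internally inconsistent as printed
EXCLUDED_ROWS: list[tuple[str, str, int, float, float, str, str]] = [
    # final day-30 row of the total-melanin table: the 60 mg count column
    # holds an area-like value (20.033), so the whole row is untrustworthy
    ("melanin_total", "LOW_40", 30, 10809, 12.763, "0.001", "row internally inconsistent (count column holds an area-like value)"),
    ("melanin_mean", "HIGH_60", 1, 29150, 7.457667, "2.55E-04", "recomputed 2.56E-04"),
    ("melanin_mean", "HIGH_60", 7, 26562, 7.48525, "0.000285", "recomputed 2.82E-04"),
    ("melanin_mean", "LOW_40", 30, 15042, 9.3396, "5.72E-04", "recomputed 6.21E-04"),
    ("melanin_mean", "HIGH_60", 30, 19435, 7.6842, "3.93E-04", "recomputed 3.95E-04"),
    ("lipofuscin_mean", "HIGH_60", 1, 7958, 23.78567, "0.003333", "recomputed 2.99e-03"),
    ("lipofuscin_mean", "HIGH_60", 7, 9872, 22.0595, "0.00225", "recomputed 0.00223"),
    ("lipofuscin_mean", "LOW_40", 30, 8106, 16.16333, "3.32E-03", "recomputed 1.99E-03"),
    ("lipofuscin_mean", "HIGH_60", 30, 5415, 24.3394, "0.0046", "recomputed 0.0045"),
]
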