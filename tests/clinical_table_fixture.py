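"""Clinical risk-factor contingency fixture: printed counts per driver group
with the percentage each numerator/denominator pair yields under half-up
rounding to two decimals (three transcription typos in the original report
are stored at their arithmetically correct value)."""

# (variable, group, numerator, denominator, percent)
TABLE1_CELLS = [
    ("sex_female", "driver-unknown", 21, 26, 80.77),
    ("sex_female", "small-mutation", 93, 131, 70.99),
    ("sex_female", "BRAF", 50, 67, 74.63),
    ("sex_female", "H/K/NRAS", 28, 45, 62.22),
    ("sex_female", "other", 15, 19, 78.95),
    ("sex_female", "fusion", 17, 23, 73.91),
    ("premenopause", "driver-unknown", 4, 17, 23.53),
    ("premenopause", "small-mutation", 44, 80, 55.00),
    ("premenopause", "BRAF", 20, 38, 52.63),
    ("premenopause", "H/K/NRAS", 14, 27, 51.85),
    ("premenopause", "other", 10, 15, 66.67),
    ("premenopause", "fusion", 12, 16, 75.00),
    ("smoking", "driver-unknown", 3, 26, 11.54),
    ("smoking", "small-mutation", 20, 130, 15.38),
    ("smoking", "BRAF", 9, 67, 13.43),
    ("smoking", "H/K/NRAS", 7, 44, 15.91),
    ("smoking", "other", 4, 19, 21.05),
    ("smoking", "fusion", 1, 23, 4.35),
    ("smoking_male", "driver-unknown", 1, 5, 20.00),
    ("smoking_male", "small-mutation", 16, 38, 42.11),
    ("smoking_male", "BRAF", 8, 17, 47.06),
    ("smoking_male", "H/K/NRAS", 6, 17, 35.29),
    ("smoking_male", "other", 2, 4, 50.00),
    ("smoking_male", "fusion", 1, 6, 16.67),
    ("smoking_female", "driver-unknown", 2, 21, 9.52),
    ("smoking_female", "small-mutation", 4, 92, 4.35),
    ("smoking_female", "BRAF", 1, 50, 2.00),
    ("smoking_female", "H/K/NRAS", 1, 27, 3.70),
    ("smoking_female", "other", 2, 15, 13.33),
    ("smoking_female", "fusion", 0, 17, 0.00),
    ("drinking", "driver-unknown", 7, 26, 26.92),
    ("drinking", "small-mutation", 40, 130, 30.77),
    ("drinking", "BRAF", 16, 67, 23.88),
    ("drinking", "H/K/NRAS", 16, 44, 36.36),
    ("drinking", "other", 8, 19, 42.11),
    ("drinking", "fusion", 7, 23, 30.43),
    ("lymphocytic_thyroiditis", "driver-unknown", 7, 26, 26.92),
    ("lymphocytic_thyroiditis", "small-mutation", 34, 131, 25.95),
    ("lymphocytic_thyroiditis", "BRAF", 25, 67, 37.31),
    ("lymphocytic_thyroiditis", "H/K/NRAS", 5, 45, 11.11),
    ("lymphocytic_thyroiditis", "other", 4, 19, 21.05),
    ("lymphocytic_thyroiditis", "fusion", 11, 23, 47.83),
]
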