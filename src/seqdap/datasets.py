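"""Small built-in sequence datasets used by worked examples and tests.

The KNU promoter EMSA probes: a 96-bp fragment of the Arabidopsis
KNUCKLES promoter carrying one strong CArG box (CCATGTTTGG) and two
adjacent, overlapping weak CArG boxes (TCTTCTTTGT / CTTCTTTGTG) located
45 and 46 bp downstream (center-to-center). The modified probes shift the
intersite spacing by −5, −10, +5 or +10 bp while keeping the probe length
at 96 bp by trimming/extending the extremities.
"""

KNU_PROBES: dict[str, str] = {
    "WT": "GGTAAGAGAAACATAGAAACCTTCCATGTTTGGCAATTTCATCTTGGAACTTGATTCACTCTCTCTTGTCTTCTTTGTGCATCACAAGAACAACAA",
    "-5": "AGAGGGTAAGAGAAACATAGAAACCTTCCATGTTTGGCAATTTCATCTTGGAACTTACTCTCTCTTGTCTTCTTTGTGCATCACAAGAACAACAAA",
    "-10": "GAAAGAGGGTAAGAGAAACATAGAAACCTTCCATGTTTGGCAATTTCATCTTGGACTCTCTCTTGTCTTCTTTGTGCATCACAAGAACAACAAATA",
    "+5": "AGAGAAACATAGAAACCTTCCATGTTTGGCAATTTCATCTTGGAAGTCAGCTTGATTCACTCTCTCTTGTCTTCTTTGTGCATCACAAGAACAACA",
    "+10": "AAACATAGAAACCTTCCATGTTTGGCAATTTCATCTTGGAAGTCAGTAGCTCTTGATTCACTCTCTCTTGTCTTCTTTGTGCATCACAAGAACAAC",
}

KNU_STRONG_BOX = "CCATGTTTGG"
KNU_WEAK_BOXES = ("TCTTCTTTGT", "CTTCTTTGTG")
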