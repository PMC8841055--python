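"""Published reference figures used as frozen expected values in tests.

All numbers are transcribed from the published application of the costing
method to Brazil (survey year 2015) and Ghana (2017): the weekly transfer
amounts per welfare measure, the eligible-women counts, and the full
48-cell annual cost grid (total cost and cost per woman, by country,
weeks covered, welfare measure and currency base).
"""

ADMIN_RATE = {"brazil": "0.056", "ghana": "0.058"}

ELIGIBLE_WOMEN = {"brazil": 291_699, "ghana": 434_410}

# Weekly cash transfer per (country, measure, currency), as printed.
WEEKLY_CT = {
    ("brazil", "minimum_wage", "USD"): "58.3",
    ("brazil", "minimum_wage", "PPP"): "106.6",
    ("brazil", "poverty_line", "USD"): "23.6",
    ("brazil", "poverty_line", "PPP"): "43.2",
    ("brazil", "twice_poverty_line", "USD"): "47.3",
    ("brazil", "twice_poverty_line", "PPP"): "86.4",
    ("ghana", "minimum_wage", "USD"): "11.7",
    ("ghana", "minimum_wage", "PPP"): "32.6",
    ("ghana", "poverty_line", "USD"): "6.8",
    ("ghana", "poverty_line", "PPP"): "18.9",
    ("ghana", "twice_poverty_line", "USD"): "13.5",
    ("ghana", "twice_poverty_line", "PPP"): "37.8",
}

# (country, weeks, measure, currency) -> (printed total cost, printed per-woman cost)
COST_GRID = {
    ("brazil", 12, "minimum_wage", "USD"): (215_430_093, 739),
    ("ghana", 12, "minimum_wage", "USD"): (64_374_448, 148),
    ("brazil", 12, "minimum_wage", "PPP"): (393_709_016, 1_350),
    ("ghana", 12, "minimum_wage", "PPP"): (179_716_519, 414),
    ("brazil", 12, "poverty_line", "USD"): (87_357_703, 299),
    ("ghana", 12, "poverty_line", "USD"): (37_326_468, 86),
    ("brazil", 12, "poverty_line", "PPP"): (159_650_467, 547),
    ("ghana", 12, "poverty_line", "PPP"): (104_205_673, 240),
    ("brazil", 12, "twice_poverty_line", "USD"): (174_715_407, 599),
    ("ghana", 12, "twice_poverty_line", "USD"): (74_652_936, 172),
    ("brazil", 12, "twice_poverty_line", "PPP"): (319_300_935, 1_095),
    ("ghana", 12, "twice_poverty_line", "PPP"): (208_411_347, 480),
    ("brazil", 14, "minimum_wage", "USD"): (251_335_094, 862),
    ("ghana", 14, "minimum_wage", "USD"): (75_103_525, 173),
    ("brazil", 14, "minimum_wage", "PPP"): (459_327_163, 1_575),
    ("ghana", 14, "minimum_wage", "PPP"): (209_669_277, 483),
    ("brazil", 14, "poverty_line", "USD"): (101_917_323, 349),
    ("ghana", 14, "poverty_line", "USD"): (43_547_547, 100),
    ("brazil", 14, "poverty_line", "PPP"): (186_258_883, 639),
    ("ghana", 14, "poverty_line", "PPP"): (121_573_291, 280),
    ("brazil", 14, "twice_poverty_line", "USD"): (203_834_646, 699),
    ("ghana", 14, "twice_poverty_line", "USD"): (87_095_094, 200),
    ("brazil", 14, "twice_poverty_line", "PPP"): (372_517_766, 1_277),
    ("ghana", 14, "twice_poverty_line", "PPP"): (243_146_581, 560),
    ("brazil", 18, "minimum_wage", "USD"): (323_145_120, 1_108),
    ("ghana", 18, "minimum_wage", "USD"): (96_561_673, 222),
    ("brazil", 18, "minimum_wage", "PPP"): (590_563_489, 2_025),
    ("ghana", 18, "minimum_wage", "PPP"): (269_574_779, 621),
    ("brazil", 18, "poverty_line", "USD"): (131_036_559, 449),
    ("ghana", 18, "poverty_line", "USD"): (55_989_704, 129),
    ("brazil", 18, "poverty_line", "PPP"): (239_475_716, 821),
    ("ghana", 18, "poverty_line", "PPP"): (156_308_517, 360),
    ("brazil", 18, "twice_poverty_line", "USD"): (262_073_119, 898),
    ("ghana", 18, "twice_poverty_line", "USD"): (111_979_409, 258),
    ("brazil", 18, "twice_poverty_line", "PPP"): (478_951_432, 1_642),
    ("ghana", 18, "twice_poverty_line", "PPP"): (312_617_034, 720),
    ("brazil", 26, "minimum_wage", "USD"): (466_765_205, 1_600),
    ("ghana", 26, "minimum_wage", "USD"): (139_477_979, 321),
    ("brazil", 26, "minimum_wage", "PPP"): (853_036_213, 2_924),
    ("ghana", 26, "minimum_wage", "PPP"): (389_385_808, 896),
    ("brazil", 26, "poverty_line", "USD"): (189_275_038, 649),
    ("ghana", 26, "poverty_line", "USD"): (80_874_015, 186),
    ("brazil", 26, "poverty_line", "PPP"): (345_909_370, 1_186),
    ("ghana", 26, "poverty_line", "PPP"): (225_778_962, 520),
    ("brazil", 26, "twice_poverty_line", "USD"): (378_550_076, 1_298),
    ("ghana", 26, "twice_poverty_line", "PPP"): (451_557_923, 1_039),
    ("ghana", 26, "twice_poverty_line", "USD"): (161_748_030, 372),
    ("brazil", 26, "twice_poverty_line", "PPP"): (691_818_740, 2_372),
}

# Cells whose per-woman value reconstructs exactly from the printed weekly
# CT: round(CT x weeks x (1 + admin_rate)) equals the printed cell.
EXACT_PER_WOMAN_CELLS = [
    ("brazil", 12, "minimum_wage", "USD", 739),
    ("brazil", 12, "poverty_line", "USD", 299),
    ("brazil", 12, "poverty_line", "PPP", 547),
    ("brazil", 12, "twice_poverty_line", "USD", 599),
    ("brazil", 12, "twice_poverty_line", "PPP", 1_095),
    ("brazil", 14, "minimum_wage", "USD", 862),
    ("brazil", 14, "poverty_line", "PPP", 639),
    ("brazil", 18, "poverty_line", "USD", 449),
    ("brazil", 26, "poverty_line", "PPP", 1_186),
    ("brazil", 26, "twice_poverty_line", "PPP", 2_372),
    ("ghana", 12, "minimum_wage", "PPP", 414),
    ("ghana", 12, "poverty_line", "USD", 86),
    ("ghana", 12, "poverty_line", "PPP", 240),
    ("ghana", 12, "twice_poverty_line", "PPP", 480),
    ("ghana", 18, "twice_poverty_line", "PPP", 720),
    ("ghana", 26, "poverty_line", "PPP", 520),
]

# GDP-share ranges of the annual program cost, percent of GDP.
GDP_SHARE_RANGE_PCT = {"brazil": (0.004, 0.02), "ghana": (0.076, 0.28)}
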