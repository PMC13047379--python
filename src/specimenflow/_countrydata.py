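"""Small built-in ISO 3166-1 alpha-3 table used by the synthetic generator.

Not a complete registry — just a pool of real codes and English short names
large enough to synthesise plausible occurrence tables and lookup files.
"""

ISO3_COUNTRIES: list[tuple[str, str]] = [
    ("ARG", "Argentina"),
    ("AUS", "Australia"),
    ("AUT", "Austria"),
    ("BEL", "Belgium"),
    ("BOL", "Bolivia"),
    ("BRA", "Brazil"),
    ("BWA", "Botswana"),
    ("CAN", "Canada"),
    ("CHE", "Switzerland"),
    ("CHL", "Chile"),
    ("CHN", "China"),
    ("CMR", "Cameroon"),
    ("COD", "Democratic Republic of the Congo"),
    ("COG", "Republic of the Congo"),
    ("COL", "Colombia"),
    ("CRI", "Costa Rica"),
    ("CZE", "Czechia"),
    ("DEU", "Germany"),
    ("DNK", "Denmark"),
    ("ECU", "Ecuador"),
    ("EGY", "Egypt"),
    ("ESP", "Spain"),
    ("ETH", "Ethiopia"),
    ("FIN", "Finland"),
    ("FRA", "France"),
    ("GAB", "Gabon"),
    ("GBR", "United Kingdom"),
    ("GHA", "Ghana"),
    ("GRC", "Greece"),
    ("GTM", "Guatemala"),
    ("HND", "Honduras"),
    ("HUN", "Hungary"),
    ("IDN", "Indonesia"),
    ("IND", "India"),
    ("IRN", "Iran"),
    ("ITA", "Italy"),
    ("JPN", "Japan"),
    ("KAZ", "Kazakhstan"),
    ("KEN", "Kenya"),
    ("KHM", "Cambodia"),
    ("KOR", "South Korea"),
    ("LAO", "Laos"),
    ("MAR", "Morocco"),
    ("MDG", "Madagascar"),
    ("MEX", "Mexico"),
    ("MMR", "Myanmar"),
    ("MNG", "Mongolia"),
    ("MOZ", "Mozambique"),
    ("MYS", "Malaysia"),
    ("NAM", "Namibia"),
    ("NGA", "Nigeria"),
    ("NLD", "Netherlands"),
    ("NOR", "Norway"),
    ("NPL", "Nepal"),
    ("NZL", "New Zealand"),
    ("PAK", "Pakistan"),
    ("PAN", "Panama"),
    ("PER", "Peru"),
    ("PHL", "Philippines"),
    ("PNG", "Papua New Guinea"),
    ("POL", "Poland"),
    ("PRT", "Portugal"),
    ("PRY", "Paraguay"),
    ("ROU", "Romania"),
    ("RUS", "Russia"),
    ("SWE", "Sweden"),
    ("THA", "Thailand"),
    ("TUR", "Turkey"),
    ("TZA", "Tanzania"),
    ("UGA", "Uganda"),
    ("UKR", "Ukraine"),
    ("URY", "Uruguay"),
    ("USA", "United States"),
    ("VEN", "Venezuela"),
    ("VNM", "Vietnam"),
    ("ZAF", "South Africa"),
    ("ZMB", "Zambia"),
    ("ZWE", "Zimbabwe"),
]

ISO3_CODES: list[str] = [c for c, _ in ISO3_COUNTRIES]
ISO3_NAMES: dict[str, str] = dict(ISO3_COUNTRIES)
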