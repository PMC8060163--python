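"""Reference camp-level land-visitation table (12 hunter-gatherer camps).

Published camp-by-camp raster areas of land visited by gender (km^2), used
to validate the aggregation conventions of the camp summary table and the
exact paired signed-rank test.  Columns: camp, year, total land visited,
male-visited, female-visited, male:female ratio, visited by both genders.
"""

import pandas as pd

CAMP_LAND_TABLE = pd.DataFrame(
    [
        ("Setako", 2009, 552.7, 462.1, 156.9, 2.9, 66.2),
        ("Setako", 2010, 281.4, 223.3, 97.3, 2.3, 39.2),
        ("Sengeli", 2010, 510.3, 485.7, 57.9, 8.4, 33.4),
        ("Sanola", 2014, 656.7, 594.1, 172.9, 3.4, 110.4),
        ("Sengeli", 2015, 548.4, 453.9, 137.2, 3.3, 42.7),
        ("Buruku", 2015, 434.4, 371.2, 121.8, 3.0, 58.6),
        ("Buruku", 2016, 622.7, 585.0, 96.8, 6.0, 59.1),
        ("Hukumako", 2016, 1200.7, 1109.7, 319.6, 3.5, 228.7),
        ("Kideru Juu", 2016, 539.0, 480.8, 124.1, 3.9, 65.9),
        ("Hukumako", 2017, 344.3, 282.4, 131.7, 2.1, 69.8),
        ("Ol Piro", 2018, 885.9, 845.9, 125.8, 6.7, 85.8),
        ("Hukumako", 2018, 360.1, 287.2, 157.4, 1.8, 84.5),
    ],
    columns=["camp_id", "year", "total_km2", "male_km2", "female_km2", "ratio", "both_km2"],
)
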