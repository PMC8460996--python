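"""Sibling-group label categories (SLC) from roster + birth-history tables.

Shows the three labelling rules: most severe tested genotype within a
full-sibling group, the Trait cap for SCD half-sibling labels, and the
promotion of AA groups with SCD half-siblings.
"""

import pandas as pd

from scdmort import assign_slc, link_siblings

roster = pd.DataFrame(
    [
        # household 1: two tested full siblings, one AA and one SS
        dict(stratum_id=0, cluster_id=0, household_id=1, child_id="a1",
             mother_id=None, zone="NW", urban=0, age_months=24, alive=True,
             age_at_death_months=None, genotype="AA", weight=1.0),
        dict(stratum_id=0, cluster_id=0, household_id=1, child_id="a2",
             mother_id=None, zone="NW", urban=0, age_months=40, alive=True,
             age_at_death_months=None, genotype="SS", weight=1.0),
        # household 2: a tested AS child
        dict(stratum_id=0, cluster_id=0, household_id=2, child_id="b1",
             mother_id=None, zone="NW", urban=0, age_months=30, alive=True,
             age_at_death_months=None, genotype="AS", weight=1.0),
    ]
)
birth_history = pd.DataFrame(
    [
        dict(mother_id="m1", household_id=1, child_id="a1",
             birth_offset_months=24, alive=True, age_at_death_months=None),
        dict(mother_id="m1", household_id=1, child_id="a2",
             birth_offset_months=40, alive=True, age_at_death_months=None),
        # an older untested full sibling of a1/a2
        dict(mother_id="m1", household_id=1, child_id="a3",
             birth_offset_months=90, alive=False, age_at_death_months=18),
        # a half-sibling of a1/a2: same mother, different household
        dict(mother_id="m1", household_id=9, child_id="a4",
             birth_offset_months=100, alive=True, age_at_death_months=None),
        dict(mother_id="m2", household_id=2, child_id="b1",
             birth_offset_months=30, alive=True, age_at_death_months=None),
    ]
)

children = assign_slc(link_siblings(roster, birth_history))
print(children[["child_id", "sibling_group_id", "tested", "slc_label"]].to_string(index=False))
# a1-a3 share household and mother -> full siblings; the SS test result makes
# their group "SCD". a4 shares only the mother -> half-sibling; it inherits
# the label capped at "Trait". b1's group is "Trait" from its own AS result.
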