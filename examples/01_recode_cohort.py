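"""Recode a small cohort table into binary indicator variables.

Builds a 9-person cohort with one continuous risk factor (BMI), one SNP in
three genotypic classes and a smoking flag, then expands every variable
into mutually exclusive 0/1 category columns — tertiles for the continuous
trait, the three genotype classes for the SNP, a yes/no pair for smoking —
plus the complementary Event/No_Event outcome pair.
"""

import numpy as np
import pandas as pd

from cohortnet import CohortTable, VariableSpec, expand_indicators, tertile_bin

values = pd.DataFrame(
    {
        "bmi": [21.5, 24.1, 27.3, 30.2, 19.8, 26.0, 33.1, 22.7, 28.9],
        "LIPC": [0, 1, 2, 1, 0, 0, 2, 1, 1],
        "smoking": [0, 1, 1, 0, 0, 1, 1, 0, 0],
    }
)
cohort = CohortTable(
    individuals=[f"p{i}" for i in range(9)],
    variables=[
        VariableSpec("bmi", "continuous"),
        VariableSpec("LIPC", "genotype3"),
        VariableSpec("smoking", "binary"),
    ],
    values=values,
    outcome=np.array([0, 1, 1, 1, 0, 0, 1, 0, 0]),
)

print("BMI tertiles:", tertile_bin(values["bmi"].to_numpy()))
matrix = expand_indicators(cohort, include_outcome=True)
print(matrix.data.to_string())
print(
    f"\n{matrix.data.shape[1]} indicator columns; each parent variable's "
    "columns sum to exactly 1 per row (complete, exclusive categories), "
    "and Event + No_Event = 1 mirrors the follow-up outcome."
)
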