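"""Build dietary and microbial δ¹³C end members for each diet × amino acid.

The dietary end member mixes casein and corn protein by the amount of each
amino acid they contribute; the microbial end member is the carbohydrate
pool δ¹³C plus a per-compound fractionation offset. Prints the end-member
separation per treatment — the quantity that determines how identifiable
the mixing fraction is.
"""

import argparse

import pandas as pd

from gutaa.aminoacids import ESSENTIAL_AA
from gutaa.endmembers import (
    DEFAULT_CASEIN_PROFILE,
    DEFAULT_CORNMEAL_PROFILE,
    DEFAULT_DIETS,
    DEFAULT_FRACTIONATION,
    build_endmember_set,
    carbohydrate_pool_delta,
    protein_source_fractions,
)
from gutaa.io import write_endmembers


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results/endmembers.tsv")
    args = ap.parse_args()

    em = build_endmember_set(DEFAULT_DIETS, DEFAULT_CASEIN_PROFILE,
                             DEFAULT_CORNMEAL_PROFILE, DEFAULT_FRACTIONATION)
    write_endmembers(em, args.out)

    rows = []
    for diet in DEFAULT_DIETS:
        f_cas, f_corn = protein_source_fractions(diet)
        seps = [abs(em.delta_microbial[(diet.treatment_label, aa)]
                    - em.delta_dietary[(diet.treatment_label, aa)])
                for aa in ESSENTIAL_AA]
        rows.append({
            "treatment": diet.treatment_label,
            "f_corn_protein": round(f_corn, 3),
            "carb_pool_delta": round(carbohydrate_pool_delta(diet), 2),
            "min_separation": round(min(seps), 2),
            "max_separation": round(max(seps), 2),
        })
    print(pd.DataFrame(rows).to_string(index=False))
    print(f"\nend members written to {args.out}")
    print("note: the low-protein diet draws ~43% of its protein from cornmeal,")
    print("pulling its dietary end member toward the C4 pool and shrinking the")
    print("separation — mixing estimates are least precise there.")


if __name__ == "__main__":
    main()
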