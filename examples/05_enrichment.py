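"""Gene-set over-representation on a hit list with planted annotation terms.

Builds a gene-set collection in which one term overlaps a 36-gene hit list
exactly as the published sulfur-metabolism signal does (10 of 93 term genes
among 36 hits, background 5135) and one term is unrelated, then computes
the enrichment table: fold enrichment, hypergeometric p, BH q.
"""

from barseqfit import enrich_table, generate_annotations

universe = [f"gene{i}" for i in range(5135)]
hits = universe[:36]

collection = generate_annotations(
    universe,
    hits,
    planted_terms={
        "sulfur_metabolism_like": (93, 10),  # printed: 15-fold enrichment
        "unrelated_process": (120, 0),
        "tight_pathway": (4, 3),             # computed: 107-fold
    },
    seed=5,
)

table = enrich_table(hits, collection, background=5135, alpha=0.01)
cols = ["term", "k", "K", "fold_enrichment", "fold_rounded", "p_value", "q_value", "significant"]
print(
    table[cols].to_string(
        index=False,
        formatters={
            "fold_enrichment": "{:.2f}".format,
            "p_value": "{:.2e}".format,
            "q_value": "{:.2e}".format,
        },
    )
)
print("\nFold enrichment is (k/n)/(K/N): hits-in-term over its background"
      "\nrate.  The 10-of-93 term reproduces the published 15-fold signal;"
      "\nterms without hits are dropped from the table.")
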