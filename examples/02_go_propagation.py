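"""Propagate GO annotation up the DAG and across a homology set.

A direct hit on a leaf term also hits every ancestor (true-path rule), and
a homology set inherits the union of its member genes' hits -- so one
annotated gene is enough to classify the whole set, and unannotated member
genes inherit the set-level terms for gene-level analyses.
"""

from fracres import HomologySet, annotate_sets
from fracres.simulate import toy_dag

dag = toy_dag()
bp_categories = dag.top_level_categories("biological_process")
print(f"toy ontology: {len(dag)} terms, top-level biological_process "
      f"categories: {bp_categories}")

leaf = "GO:1010200"  # a leaf below the first biological_process category
print(f"\nancestor closure of {leaf}:")
for t in sorted(dag.ancestors(leaf)):
    print(f"  {t}  {dag.terms[t].name}")

hset = HomologySet("anc_042", {"sp1": ["sp1_a", "sp1_b"], "sp2": ["sp2_a"]})
amap = annotate_sets([hset], {"sp1_a": {leaf}}, dag)
print(f"\nset-level terms of {hset.set_id} (from one annotated gene):")
print(" ", sorted(amap.set_terms("anc_042")))
print("terms inherited by the unannotated gene sp2_a:")
print(" ", sorted(amap.gene_terms("sp2_a")))
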