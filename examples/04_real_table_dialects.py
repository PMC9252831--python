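"""Read real-world table dialects: a DESeq2 export and a TargetScan-style
summary, with background restriction and miRNA-expression filtering.

Writes tiny example files to a temp directory first, so the script is
self-contained; point the readers at your own exports in practice.
"""

import tempfile
from pathlib import Path

import mirten as M

tmp = Path(tempfile.mkdtemp())

# a DESeq2-style differential expression export
(tmp / "dea.csv").write_text(
    "gene,baseMean,log2FoldChange,pvalue,padj\n"
    "Actb,5000,-0.1,0.6,0.9\n"
    "Foxo1,800,-1.4,0.0002,0.004\n"
    "Gria1,650,-0.9,0.001,0.01\n"
    "Nrn1,90,0.3,0.2,0.5\n"
    "Dcx,40,-1.1,0.03,0.2\n"
)
# a TargetScan-style summary table (family-level annotation)
(tmp / "targetscan.tsv").write_text(
    "miR Family\tGene Symbol\tTotal num conserved sites\t"
    "Total num nonconserved sites\tCumulative weighted context++ score\n"
    "miR-129-5p\tFoxo1\t2\t1\t-0.61\n"
    "miR-129-5p\tGria1\t1\t0\t-0.32\n"
    "miR-137\tDcx\t0\t2\t-0.15\n"
    "miR-137\tActb\t1\t0\t-0.05\n"
)

dea = M.read_dea(tmp / "dea.csv")
dea = M.restrict_background(dea, top_n=4)  # highest-expressed background
tc = M.read_targetscan(tmp / "targetscan.tsv", conserved_only=True)
tc = M.filter_regulators(tc, {"miR-129-5p": 120.0, "miR-137": 80.0}, min_expr=50)

res = M.run_enrichment(dea, tc, "overlap", M.TestConfig(sel_alpha=0.05))
print(res[["regulator", "n_targets", "n_selected_targets", "pvalue", "fdr"]].to_string(index=False))

# With conserved_only=True, miR-137 loses its Dcx row (0 conserved sites);
# the background keeps the 4 highest-expressed genes, and the selected set
# defaults to genes at FDR < 0.05 and downregulated.
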