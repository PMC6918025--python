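"""poolfit: pooled barcoded-mutant fitness, FPKM expression, and their integration.

A reusable implementation of the functional-genomics inference used to map
carbon-utilization pathways in *Rhodosporidium toruloides*: barcode-based
mutant-pool fitness scoring with a consistency T-statistic, FPKM differential
expression with hierarchical clustering, an expression-by-fitness quadrant
filter for candidate-gene calling, and Michaelis-Menten enzyme kinetics.
Synthetic generators with planted ground truth make every stage testable.
"""

from importlib.resources import files as _files

import pandas as _pd

from .barcode_counts import (
    CountMatrix,
    FlankConfig,
    count_barcodes,
    extract_barcode,
)
from .expression_analysis import (
    bh_adjust,
    cluster_genes,
    condition_means,
    differential_test,
    expression_table,
    fpkm,
    max_fold_change,
    prefilter_genes,
    read_expression_table,
    write_expression_table,
)
from .fitness_analysis import (
    GeneFitness,
    build_observation_table,
    fit_gene_fitness,
    gene_fitness,
    gene_t_statistic,
    normalize_fitness,
    observation_weights,
    read_gene_fitness,
    relative_fitness,
    strain_fitness,
    write_gene_fitness,
)
from .integration import (
    FilterThresholds,
    candidate_table,
    expression_pass,
    fitness_pass,
    scatter_export,
)
from .kinetics import (
    MMFit,
    NADPH_EPSILON_340,
    fit_michaelis_menten,
    michaelis_menten,
    rate_from_absorbance,
    read_rate_table,
    write_rate_table,
)
from .pool_model import (
    Gene,
    Insertion,
    InsertionPool,
    assign_insertions,
    read_gene_annotation,
    read_pool_table,
    write_gene_annotation,
    write_pool_table,
)
from .synthetic_data import (
    DEFAULT_FLANKS,
    SimConfig,
    TruthTable,
    simulate_barseq_counts,
    simulate_fastq,
    simulate_mm_assay,
    simulate_pool,
    simulate_rnaseq_counts,
)

__version__ = "0.1.0"


def load_dgalua_candidates() -> _pd.DataFrame:
    """Published per-gene summary for the *R. toruloides* d-galUA study.

    Mean FPKM and gene fitness scores on d-galacturonate, glycerol and
    d-glucose for the seven genes called specifically induced on and
    required for growth on d-galUA (transporter, pathway enzymes GAR1 /
    GaaB / GaaC / GaaD, GAL7, and a ZnCys transcription factor).
    """
    path = _files("poolfit").joinpath("data/dgalua_candidates.tsv")
    return _pd.read_csv(path, sep="\t", index_col="gene_id")
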