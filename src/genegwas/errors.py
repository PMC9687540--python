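"""Exception hierarchy for genegwas."""


class GeneGwasError(Exception):
    """Base class for all genegwas errors."""


class ParseError(GeneGwasError, ValueError):
    """A file did not conform to its declared dialect."""


class EmptyPanelError(GeneGwasError, ValueError):
    """A genotype source yielded no usable records."""


class DegenerateGeneError(GeneGwasError, ValueError):
    """All SNP columns of a gene are monomorphic within the sample."""


class DegeneratePhenotypeError(GeneGwasError, ValueError):
    """Phenotype has no variance (or no usable values)."""
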