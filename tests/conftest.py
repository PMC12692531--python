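import numpy as np
import pytest

from carpoligo import synthetic, transcriptome

# a 40-nt contig used by the hand-built annotation fixtures
CONTIG_A = "ACGTACGTACCCGGTTAAGGACGTTGCACAGGTTACAGTC"
CONTIG_B = "TTGACCGTAGGCATCCATGGCAATCGGATCTTACGGACCA"

GFF3_SMALL = """##gff-version 3
chrA\ttest\tgene\t1\t40\t.\t+\t.\tID=geneA
chrA\ttest\tmRNA\t1\t30\t.\t+\t.\tID=txA1;Parent=geneA;biotype=mRNA
chrA\ttest\texon\t1\t10\t.\t+\t.\tID=txA1.e1;Parent=txA1
chrA\ttest\texon\t21\t30\t.\t+\t.\tID=txA1.e2;Parent=txA1
chrA\ttest\tmRNA\t1\t30\t.\t+\t.\tID=txA2;Parent=geneA
chrA\ttest\texon\t1\t30\t.\t+\t.\tID=txA2.e1;Parent=txA2
chrB\ttest\tgene\t1\t40\t.\t-\t.\tID=geneB
chrB\ttest\tncRNA\t5\t24\t.\t-\t.\tID=txB1;Parent=geneB;biotype=ncRNA
chrB\ttest\texon\t5\t24\t.\t-\t.\tID=txB1.e1;Parent=txB1
"""


@pytest.fixture()
def small_annotation(tmp_path):
    """Two genes, three transcripts, on two 40-nt contigs."""
    fasta = tmp_path / "genome.fa"
    fasta.write_text(f">chrA\n{CONTIG_A}\n>chrB\n{CONTIG_B}\n")
    gff = tmp_path / "genes.gff3"
    gff.write_text(GFF3_SMALL)
    return fasta, gff


@pytest.fixture()
def small_transcripts(small_annotation):
    fasta, gff = small_annotation
    return transcriptome.load_transcriptome(fasta, gff)


@pytest.fixture()
def rng():
    return np.random.default_rng(20251001)


@pytest.fixture(scope="session")
def tiny_synthetic(tmp_path_factory):
    """Small synthetic transcriptome with one paralog family, loaded once."""
    d = tmp_path_factory.mktemp("synth")
    params = synthetic.SyntheticTranscriptomeParams(
        n_genes=8,
        isoform_range=(1, 3),
        paralog_families=1,
        paralog_family_size=2,
        paralog_identity=0.92,
        exon_length_range=(120, 220),
        intron_length_range=(40, 80),
        seed=11,
    )
    fa, gff = synthetic.generate_transcriptome(params, d)
    ts = transcriptome.load_transcriptome(fa, gff)
    return params, ts


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
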