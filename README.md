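# genoprep

Tools for the last, least glamorous step of a whole-genome sequencing
project: turning a draft assembly (FASTA) plus its structural annotation
(GFF3) into a clean, internally consistent dataset and an NCBI
submission-ready feature table (`.tbl`), the format `tbl2asn` consumes.

Automated gene predictors routinely emit models that a repository will
reject or that deserve review — introns as short as 1 bp, coding regions
under the ~150 bp floor NCBI suggests, contigs with runs of ambiguous
bases (N) at their ends that look like scaffold gaps, and coordinates
that drift out of sync with the FASTA once anything is trimmed.
`genoprep` is aimed at the individual lab submitting its study organism's
genome: one command applies controlled filters and fixes, documents every
change, and writes all submission artifacts.

## What it does

Working on a `gene → mRNA → exon/CDS` hierarchy (1-based inclusive
coordinates throughout), the pipeline can:

- **Remove or flag** models by length criteria: CDS (total spliced
  length), exon, intron, or gene span, each with a *shorter than* /
  *longer than* bound and strict inequality, in remove or flag mode
  (16 option combinations). Flagging adds a `gag_flag=<rule>` attribute
  to GFF3 column 9 for review in a genome browser; removal detaches the
  whole owning transcript (you cannot drop one exon and keep a sane
  model) and cascades — a gene losing its last mRNA goes too, parent
  spans are recomputed from surviving children.
- **Remove by ID list** (`remove_by_id`), for when a submission comes
  back with a list of rejected features.
- **Fix start/stop codons** (`--fix_start_stop`): reads the spliced CDS
  off the actual sequence (reverse-complemented on `-`), accepts ATG as
  start and the translation-table stops (default TAA/TAG/TGA), emits
  `start_codon`/`stop_codon` features (split across exons when a codon
  straddles a junction), and records partiality for the feature table
  (`<`/`>` markers).
- **Strip terminal Ns** (`--fix_terminal_ns`) and **trim BED regions or
  whole scaffolds** (`-t`), rewriting every surviving feature's
  coordinates so the bases under it are unchanged — the invariant the
  test suite checks on thousands of random cases.
- **Merge functional annotations** — `Name` (genes), `product` (mRNAs),
  `Dbxref`, `Ontology_term` — from GFF3 column 9 or a 3-column
  tab-delimited file (`-a`), flowing to both the output GFF3 and `.tbl`.
- **Report statistics** before and after editing as two columns, and log
  the whole session (`gag.log`, `genome.removed.gff`) so the filtering
  criteria applied to a dataset stay on record.

Every run writes `genome.fasta`, `genome.gff`, `genome.removed.gff`,
`genome.stats`, `genome.tbl`, and `gag.log` into `--out`. Feature IDs are
conserved: IDs in the output GFF3 and the removed-features GFF exactly
partition the input IDs.

## Worked example

A synthetic 2-scaffold draft with planted defects (short introns, short
CDSs, leading N runs) ships with the package's fixture generator:

```sh
python -c "
import genoprep as gp
from genoprep.fixtures import write_genome, FixtureParams
g, _ = gp.make_genome(7, n_seqs=2, genes_per_seq=10,
                      params=FixtureParams(frac_short_intron=0.2,
                                           frac_short_cds=0.15,
                                           frac_lead_ns=0.5))
write_genome(g, '.', 'draft')
open('functional.tsv','w').write('gene1\tname\tcytB\n'
                                 'mrna1\tproduct\thypothetical protein\n')"

genoprep --fasta draft.fasta --gff draft.gff3 --out out \
         -a functional.tsv --fix_terminal_ns -ris 10 -rcs 150 \
         --fix_start_stop
```

The session log (`out/gag.log`) prints:

```
loaded 2 sequence(s), 20 gene(s) from draft.fasta + draft.gff3
annotate: 2 row(s), 0 warning(s)
fix_terminal_ns: 0 feature(s) removed
remove intron shorter_than 10: 4 feature(s) removed
remove cds shorter_than 150: 5 feature(s) removed
fix_start_stop: 18 start / 16 stop codon(s) confirmed
wrote genome.fasta genome.gff genome.removed.gff genome.stats genome.tbl
```

Nine features (4 mRNAs with a sub-10 bp intron plus their emptied
parents, then 5 more for sub-150 bp CDSs) moved to
`genome.removed.gff`. `out/genome.stats` shows the effect:

```
                            original      modified
Number of sequences                2             2
Total sequence length          11518         11509
Number of genes                   20            16
Number of mRNAs                   23            18
Shortest intron                    1            31
Shortest CDS                      66           201
```

— the 1 bp intron and 66 bp CDS are gone, total length dropped by the 9
stripped leading Ns. The head of `out/genome.tbl`:

```
>Feature scaffold1
73	678	gene
			gene	cytB
			locus_tag	GP_000001
73	250	mRNA
326	420
472	678
			product	hypothetical protein
```

Gene blocks carry `locus_tag` (prefix via `--locus_tag_prefix`);
minus-strand blocks list coordinates high-to-low; a CDS without a
confirmed start codon is written `<start` (5'-partial), without a stop
`>end`.

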