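mutation
mutations
variant
variants
allele
alleles
allelic
genotype
genotypes
genotyping
polymorphism
polymorphisms
substitution
substitutions
missense
nonsense
frameshift
deletion
insertion
duplication
germline
somatic
heterozygous
homozygous
zygosity
codon
exon
exons
intron
intronic
promoter
enhancer
locus
loci
haplotype
haplotypes
chromosome
chromosomal
genome
genomic
genomes
sequencing
sequenced
sequence
resequencing
exome
transcriptome
amplicon
nucleotide
nucleotides
base-pair
transition
transversion
dbsnp
rsid
hgvs
annotation
annotated
pathogenicity
penetrance
segregation
pedigree
proband
probands
carrier
carriers
inheritance
inherited
hereditary
familial
sporadic
mutant
mutated
mutational
mutagenesis
oncogene
oncogenes
tumor-suppressor
suppressor
kinase
receptor
transcription
expression
overexpression
knockdown
knockout
wildtype
wild-type
functional
dysfunction
pathway
signaling
apoptosis
proliferation
malignant
malignancy
tumor
tumors
tumour
carcinoma
adenocarcinoma
leukemia
leukemic
lymphoid
myeloid
metastasis
metastatic
prognosis
prognostic
diagnosis
diagnostic
biomarker
biomarkers
screening
cohort
cohorts
case-control
genome-wide
genotyped
imputation
linkage
association-study
susceptibility-locus
risk-allele
odds-ratio
confidence-interval
p-value
statistically
genetics
genetic
genetically
epigenetic
methylation
histone
microsatellite
instability
repair
recombination
replication
polymerase
translocation
fusion
breakpoint
karyotype
cytogenetic
fluorescence
hybridization
microarray
rna-seq
qpcr
immunohistochemistry
biopsy
biopsies
tissue
tissues
specimen
specimens
plasma
serum
blood
bone-marrow
relapse
remission
chemotherapy
radiotherapy
targeted-therapy
inhibitor
inhibitors
resistance
sensitizing
responder
responders
survival
hazard-ratio
kaplan-meier
multivariate
univariate
regression
validated
validation
replication-cohort
functional-assay
luciferase
transfection
plasmid
vector
crispr
sirna
lentiviral
xenograft
murine
transgenic
phenotype
phenotypes
phenotypic
genotype-phenotype
clinvar
cosmic
databases
curation
curated
literature-mined
variant-calling
coverage-depth
read-depth
alignment
reference-genome
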