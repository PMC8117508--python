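gene_name	protein_symbol	category	integrity
apoptosis regulator Bcl-2-like	BCL2	B-related	100
coxsackievirus and adenovirus receptor-like	CXAR	B-related	100
spindle and kinetochore-associated protein 1-like	SKA1	B-related	100
kinesin-like protein KIF11-like	KIF11	B-related	96.13
zinc finger protein 771-like	ZNF71	B-related	89.37
serine/threonine-protein kinase RIO3-like	RIOK3	B-related	81.57
ATP-binding cassette sub-family A member 1-like	ABCA1	B-related	80.25
aurora kinase A-B-like	AURKA	B-related	77.16
centromere-associated protein E-like	CENPE	B-related	73.92
zinc finger protein 836-like	ZN836	B-related	64.52
histone-lysine N-methyltransferase MLL3-like	KMT2C	B-related	56.16
butyrophilin subfamily 2 member A1-like	BT2A1	other	100
butyrophilin-like protein 2-like	BTNL2	other	100
myosin-10-like	MYH10	other	100
polymeric immunoglobulin receptor-like	PIGR	other	100
serine protease 23-like	PRS23	other	100
peptide chain release factor 1-like, mitochondrial-like	RF1ML	other	100
VIP peptides-like	VIP	other	100
zinc finger protein 879-like	ZN879	other	100
ATP-dependent RNA helicase DDX51-like	DDX51	other	92.22
CD209 antigen-like	CD209	other	90.13
protocadherin-10-like	PCD10	other	89.58
heterogeneous nuclear ribonucleoprotein Q-like	HNRPQ	other	79.90
leucine-rich repeat-containing protein 30-like	LRC30	other	71.93
synaptonemal complex protein 2-like	SYCP2	other	70.97
extracellular calcium-sensing receptor-like	CASR	other	69.46
protein NLRC3-like	NLRC3	other	68.24
guanine nucleotide-binding protein G	GNAI1	other	67.52
vascular cell adhesion protein 1-like	VCAM1	other	65.79
torsin-1A-interacting protein 2-like	ELOF1	other	64.25
zinc finger protein 782-like	ZN782	other	63.42
zinc finger protein 678-like	ZN678	other	63.01
V-set domain-containing T-cell activation inhibitor 1-like	VTCN1	other	63.00
poly [ADP-ribose] polymerase 14-like	PAR14	other	61.53
DNA-directed RNA polymerase E subunit 1-like	RPA49	other	61.01
endonuclease domain-containing 1 protein-like	ENDD1	other	58.21
SAM domain and HD domain-containing protein 1-like	ESPL1	other	57.51
targeting protein for Xklp2-A-like	TPX2	other	52.30
interferon-induced very large GTPase 1-like	GVIN1	other	51.55
sterile alpha motif domain-containing protein 12-like	SAM12	other	51.27
xylulose kinase-like	XYLB	other	50.52
glucose-6-phosphate 1-dehydrogenase-like	G6PD	other	50.43
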