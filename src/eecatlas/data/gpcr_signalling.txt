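# Curated mouse GPCR cell-signalling gene set, v1.
# Categories follow the published description of the signalling space:
# GPCRs, G-protein subunits and regulators, GPCR kinases, adenylate
# cyclases, phosphodiesterases, beta-arrestins, phospholipase C and protein
# kinase A/C isoforms, protein-kinase anchoring proteins, ion channels,
# mediators of calcium release, and ryanodine receptors.  This is the
# package's own curation of those categories (the original list is not
# public); override with --gene-set / load_signalling_gene_set(path).
# Format: symbol<TAB>category

# --- GPCRs
Ffar1	GPCR
Ffar2	GPCR
Ffar3	GPCR
Ffar4	GPCR
Gpbar1	GPCR
Gpr119	GPCR
Gpr142	GPCR
Gper1	GPCR
Casr	GPCR
Mc4r	GPCR
Sstr1	GPCR
Sstr2	GPCR
Sstr5	GPCR
Galr1	GPCR
Adgrg4	GPCR
Vipr1	GPCR
Adra2a	GPCR
Avpr1b	GPCR
Ptger3	GPCR
Cnr1	GPCR
Drd2	GPCR
Htr4	GPCR
Gipr	GPCR
Glp1r	GPCR
Gcgr	GPCR
Cckar	GPCR
Cckbr	GPCR
Grm4	GPCR
Tas1r1	GPCR
Tas1r3	GPCR
Lpar5	GPCR
S1pr1	GPCR
Sctr	GPCR
Ghsr	GPCR
Npy1r	GPCR
Agtr1a	GPCR
# --- G-protein subunits and regulators
Gnas	G-protein
Gnai1	G-protein
Gnai2	G-protein
Gnai3	G-protein
Gnaq	G-protein
Gna11	G-protein
Gna12	G-protein
Gna13	G-protein
Gnao1	G-protein
Gnb1	G-protein
Gnb2	G-protein
Gng2	G-protein
Gng4	G-protein
Rgs2	G-protein
Rgs4	G-protein
Rgs5	G-protein
Rgs16	G-protein
Ric8a	G-protein
Ric8b	G-protein
# --- GPCR kinases
Grk2	GPCR-kinase
Grk3	GPCR-kinase
Grk4	GPCR-kinase
Grk5	GPCR-kinase
Grk6	GPCR-kinase
# --- adenylate cyclases
Adcy1	adenylate-cyclase
Adcy2	adenylate-cyclase
Adcy3	adenylate-cyclase
Adcy4	adenylate-cyclase
Adcy5	adenylate-cyclase
Adcy6	adenylate-cyclase
Adcy7	adenylate-cyclase
Adcy8	adenylate-cyclase
Adcy9	adenylate-cyclase
# --- phosphodiesterases
Pde1a	phosphodiesterase
Pde1c	phosphodiesterase
Pde3a	phosphodiesterase
Pde3b	phosphodiesterase
Pde4a	phosphodiesterase
Pde4b	phosphodiesterase
Pde4d	phosphodiesterase
Pde7a	phosphodiesterase
Pde8a	phosphodiesterase
Pde10a	phosphodiesterase
# --- beta-arrestins
Arrb1	beta-arrestin
Arrb2	beta-arrestin
# --- phospholipase C isoforms
Plcb1	PLC
Plcb2	PLC
Plcb3	PLC
Plcb4	PLC
Plcg1	PLC
Plcg2	PLC
Plcd1	PLC
Plce1	PLC
# --- protein kinase A isoforms
Prkaca	PKA
Prkacb	PKA
Prkar1a	PKA
Prkar1b	PKA
Prkar2a	PKA
Prkar2b	PKA
# --- protein kinase C isoforms
Prkca	PKC
Prkcb	PKC
Prkcd	PKC
Prkce	PKC
Prkcz	PKC
# --- protein-kinase anchoring proteins
Akap1	AKAP
Akap5	AKAP
Akap9	AKAP
Akap12	AKAP
# --- ion channels
Kcnb1	ion-channel
Kcnh2	ion-channel
Kcnj3	ion-channel
Kcnj6	ion-channel
Kcnn3	ion-channel
Kcnq1	ion-channel
Scn3a	ion-channel
Scn9a	ion-channel
Cacna1a	ion-channel
Cacna1c	ion-channel
Cacna1d	ion-channel
Cacna1h	ion-channel
Cacna2d1	ion-channel
Cacnb2	ion-channel
Trpa1	ion-channel
Trpm2	ion-channel
Trpm4	ion-channel
Trpm5	ion-channel
Trpv1	ion-channel
Trpc3	ion-channel
Clcn3	ion-channel
Hcn1	ion-channel
Ano1	ion-channel
# --- mediators of calcium release
Itpr1	calcium-release
Itpr2	calcium-release
Itpr3	calcium-release
Stim1	calcium-release
Stim2	calcium-release
Orai1	calcium-release
Calm1	calcium-release
Calm2	calcium-release
Atp2a2	calcium-release
Atp2a3	calcium-release
# --- ryanodine receptors
Ryr1	ryanodine-receptor
Ryr2	ryanodine-receptor
Ryr3	ryanodine-receptor
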