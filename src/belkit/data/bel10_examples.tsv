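# Canonical BEL 1.0 expression inventory: one example per function and
# relationship as used in the corpora, in short and long spelling.
# Columns: kind (term|statement), short form, long form.
term	a(CHEBI:water)	abundance(CHEBI:water)
term	p(HGNC:IL6)	proteinAbundance(HGNC:IL6)
term	complex(NCH:"AP-1 Complex")	complexAbundance(NCH:"AP-1 Complex")
term	complex(p(MGI:Fos), p(MGI:Jun))	complexAbundance(proteinAbundance(MGI:Fos), proteinAbundance(MGI:Jun))
term	composite(p(MGI:Il13),p(MGI:Ifng))	compositeAbundance(proteinAbundance(MGI:Il13),proteinAbundance(MGI:Ifng))
term	g(HGNC:ERBB2)	geneAbundance(HGNC:ERBB2)
term	m(MGI:Mir21)	microRNAabundance(MGI:Mir21)
term	r(HGNC:IL6)	rnaAbundance(HGNC:IL6)
term	p(HGNC:AKT1, pmod(P))	proteinAbundance(HGNC:AKT1, proteinModification(P))
term	p(MGI:Rela, pmod(A, K))	proteinAbundance(MGI:Rela, proteinModification(A, K))
term	p(HGNC:HIF1A, pmod(H, N, 803))	proteinAbundance(HGNC:HIF1A, proteinModification(H, N, 803))
term	p(HGNC:PIK3CA, sub(E, 545, K))	proteinAbundance(HGNC:PIK3CA, substitution(E, 545, K))
term	p(HGNC:ABCA1, trunc(1851))	proteinAbundance(HGNC:ABCA1, truncation(1851))
term	p(HGNC:BCR, fus(HGNC:JAK2, 1875, 2626))	proteinAbundance(HGNC:BCR, fusion(HGNC:JAK2, 1875, 2626))
term	p(HGNC:BCR, fus(HGNC:JAK2))	proteinAbundance(HGNC:BCR, fusion(HGNC:JAK2))
term	deg(r(HGNC:MYC))	degradation(rnaAbundance(HGNC:MYC))
term	sec(p(MGI:Il6))	cellSecretion(proteinAbundance(MGI:Il6))
term	surf(p(RGD:Fas))	cellSurfaceExpression(proteinAbundance(RGD:Fas))
term	tloc(p(HGNC:NFE2L2), MESHCL:Cytoplasm, MESHCL:"Cell Nucleus")	translocation(proteinAbundance(HGNC:NFE2L2), MESHCL:Cytoplasm, MESHCL:"Cell Nucleus")
term	rxn(reactants(a(CHEBI:"leukotriene D4")), products(a(CHEBI:"leukotriene E4")))	reaction(reactants(abundance(CHEBI:"leukotriene D4")), products(abundance(CHEBI:"leukotriene E4")))
term	act(p(RGD:Sod1))	molecularActivity(proteinAbundance(RGD:Sod1))
term	cat(p(RGD:Sod1))	catalyticActivity(proteinAbundance(RGD:Sod1))
term	chap(p(HGNC:CANX))	chaperoneActivity(proteinAbundance(HGNC:CANX))
term	gtp(p(PFH:"RAS Family"))	gtpBoundActivity(proteinAbundance(PFH:"RAS Family"))
term	kin(p(HGNC:CHEK1))	kinaseActivity(proteinAbundance(HGNC:CHEK1))
term	pep(p(RGD:Ace))	peptidaseActivity(proteinAbundance(RGD:Ace))
term	phos(p(HGNC:DUSP1))	phosphataseActivity(proteinAbundance(HGNC:DUSP1))
term	ribo(p(HGNC:PARP1))	ribosylationActivity(proteinAbundance(HGNC:PARP1))
term	tscript(p(MGI:Trp53))	transcriptionalActivity(proteinAbundance(MGI:Trp53))
term	tport(complex(NCH:"ENaC Complex"))	transportActivity(complexAbundance(NCH:"ENaC Complex"))
term	bp(GO:"cellular senescence")	biologicalProcess(GO:"cellular senescence")
term	path(MESHD: Atherosclerosis)	pathology(MESHD: Atherosclerosis)
statement	cat(p(MGI:Crk)) -> p(MGI:Bcar1,pmod(P))	catalyticActivity(proteinAbundance(MGI:Crk)) increases proteinAbundance(MGI:Bcar1,proteinModification(P))
statement	cat(p(MGI:Crk)) => p(MGI:Bcar1,pmod(P))	catalyticActivity(proteinAbundance(MGI:Crk)) directlyIncreases proteinAbundance(MGI:Bcar1,proteinModification(P))
statement	p(HGNC:TIMP2) -| cat(p(HGNC:MMP2))	proteinAbundance(HGNC:TIMP2) decreases catalyticActivity(proteinAbundance(HGNC:MMP2))
statement	p(HGNC:TIMP2) =| cat(p(HGNC:MMP2))	proteinAbundance(HGNC:TIMP2) directlyDecreases catalyticActivity(proteinAbundance(HGNC:MMP2))
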