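population,status,marker,genotype,count
Estonia,1,rs3802842,AA,87
Estonia,1,rs3802842,AC,66
Estonia,1,rs3802842,CC,13
Estonia,0,rs3802842,AA,93
Estonia,0,rs3802842,AC,61
Estonia,0,rs3802842,CC,12
Latvia,1,rs3802842,AA,46
Latvia,1,rs3802842,AC,27
Latvia,1,rs3802842,CC,8
Latvia,0,rs3802842,AA,37
Latvia,0,rs3802842,AC,40
Latvia,0,rs3802842,CC,4
Lithuania,1,rs3802842,AA,50
Lithuania,1,rs3802842,AC,62
Lithuania,1,rs3802842,CC,11
Lithuania,0,rs3802842,AA,70
Lithuania,0,rs3802842,AC,45
Lithuania,0,rs3802842,CC,8
Poland,1,rs3802842,AA,408
Poland,1,rs3802842,AC,330
Poland,1,rs3802842,CC,57
Poland,0,rs3802842,AA,411
Poland,0,rs3802842,AC,331
Poland,0,rs3802842,CC,53
Estonia,1,rs4464148,TT,77
Estonia,1,rs4464148,TC,74
Estonia,1,rs4464148,CC,15
Estonia,0,rs4464148,TT,87
Estonia,0,rs4464148,TC,62
Estonia,0,rs4464148,CC,17
Latvia,1,rs4464148,TT,35
Latvia,1,rs4464148,TC,41
Latvia,1,rs4464148,CC,5
Latvia,0,rs4464148,TT,40
Latvia,0,rs4464148,TC,35
Latvia,0,rs4464148,CC,6
Lithuania,1,rs4464148,TT,58
Lithuania,1,rs4464148,TC,45
Lithuania,1,rs4464148,CC,20
Lithuania,0,rs4464148,TT,63
Lithuania,0,rs4464148,TC,47
Lithuania,0,rs4464148,CC,13
Poland,1,rs4464148,TT,337
Poland,1,rs4464148,TC,357
Poland,1,rs4464148,CC,101
Poland,0,rs4464148,TT,371
Poland,0,rs4464148,TC,346
Poland,0,rs4464148,CC,78
Estonia,1,rs4779584,CC,99
Estonia,1,rs4779584,CT,58
Estonia,1,rs4779584,TT,9
Estonia,0,rs4779584,CC,97
Estonia,0,rs4779584,CT,59
Estonia,0,rs4779584,TT,10
Latvia,1,rs4779584,CC,49
Latvia,1,rs4779584,CT,29
Latvia,1,rs4779584,TT,3
Latvia,0,rs4779584,CC,52
Latvia,0,rs4779584,CT,22
Latvia,0,rs4779584,TT,7
Lithuania,1,rs4779584,CC,58
Lithuania,1,rs4779584,CT,53
Lithuania,1,rs4779584,TT,12
Lithuania,0,rs4779584,CC,70
Lithuania,0,rs4779584,CT,44
Lithuania,0,rs4779584,TT,9
Poland,1,rs4779584,CC,446
Poland,1,rs4779584,CT,301
Poland,1,rs4779584,TT,48
Poland,0,rs4779584,CC,467
Poland,0,rs4779584,CT,272
Poland,0,rs4779584,TT,56
Estonia,1,rs4939827,CC,32
Estonia,1,rs4939827,CT,87
Estonia,1,rs4939827,TT,47
Estonia,0,rs4939827,CC,50
Estonia,0,rs4939827,CT,71
Estonia,0,rs4939827,TT,45
Latvia,1,rs4939827,CC,15
Latvia,1,rs4939827,CT,46
Latvia,1,rs4939827,TT,20
Latvia,0,rs4939827,CC,19
Latvia,0,rs4939827,CT,45
Latvia,0,rs4939827,TT,17
Lithuania,1,rs4939827,CC,25
Lithuania,1,rs4939827,CT,52
Lithuania,1,rs4939827,TT,46
Lithuania,0,rs4939827,CC,27
Lithuania,0,rs4939827,CT,69
Lithuania,0,rs4939827,TT,27
Poland,1,rs4939827,CC,157
Poland,1,rs4939827,CT,393
Poland,1,rs4939827,TT,245
Poland,0,rs4939827,CC,167
Poland,0,rs4939827,CT,416
Poland,0,rs4939827,TT,212
Estonia,1,rs6983267,TT,37
Estonia,1,rs6983267,TG,90
Estonia,1,rs6983267,GG,39
Estonia,0,rs6983267,TT,51
Estonia,0,rs6983267,TG,73
Estonia,0,rs6983267,GG,42
Latvia,1,rs6983267,TT,16
Latvia,1,rs6983267,TG,38
Latvia,1,rs6983267,GG,27
Latvia,0,rs6983267,TT,17
Latvia,0,rs6983267,TG,41
Latvia,0,rs6983267,GG,23
Lithuania,1,rs6983267,TT,26
Lithuania,1,rs6983267,TG,63
Lithuania,1,rs6983267,GG,34
Lithuania,0,rs6983267,TT,28
Lithuania,0,rs6983267,TG,61
Lithuania,0,rs6983267,GG,34
Poland,1,rs6983267,TT,190
Poland,1,rs6983267,TG,392
Poland,1,rs6983267,GG,213
Poland,0,rs6983267,TT,209
Poland,0,rs6983267,TG,410
Poland,0,rs6983267,GG,176
Estonia,1,rs10795668,AA,17
Estonia,1,rs10795668,AG,71
Estonia,1,rs10795668,GG,78
Estonia,0,rs10795668,AA,21
Estonia,0,rs10795668,AG,81
Estonia,0,rs10795668,GG,64
Latvia,1,rs10795668,AA,9
Latvia,1,rs10795668,AG,33
Latvia,1,rs10795668,GG,39
Latvia,0,rs10795668,AA,5
Latvia,0,rs10795668,AG,40
Latvia,0,rs10795668,GG,36
Lithuania,1,rs10795668,AA,12
Lithuania,1,rs10795668,AG,59
Lithuania,1,rs10795668,GG,52
Lithuania,0,rs10795668,AA,13
Lithuania,0,rs10795668,AG,56
Lithuania,0,rs10795668,GG,54
Poland,1,rs10795668,AA,88
Poland,1,rs10795668,AG,325
Poland,1,rs10795668,GG,382
Poland,0,rs10795668,AA,96
Poland,0,rs10795668,AG,360
Poland,0,rs10795668,GG,339
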