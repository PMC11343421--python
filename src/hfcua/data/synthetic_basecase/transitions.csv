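arm,period,from_state,Q1,Q2,Q3,Q4
EPG_SOC,m1_3,Q1,0.35641771131758149,0.47876296489551357,0.11713596442247198,0.047683359364433048
EPG_SOC,m1_3,Q2,0.2330674994379712,0.44479893488754074,0.25495864757391534,0.067174918100572578
EPG_SOC,m1_3,Q3,0.037269234522289446,0.24041873357976667,0.44302460811810862,0.27928742377983529
EPG_SOC,m1_3,Q4,0.016942784138056916,0.069587461259684624,0.42474579541808982,0.48872395918416867
EPG_SOC,m4_8,Q1,0.58091168767653334,0.32394962803406196,0.070639978125274325,0.024498706164130347
EPG_SOC,m4_8,Q2,0.14190118806522101,0.63168070852849467,0.17097714622835333,0.055440957177931065
EPG_SOC,m4_8,Q3,0.045672086314496582,0.17327645358182883,0.62935826387178262,0.15169319623189198
EPG_SOC,m4_8,Q4,0.011392841404568086,0.042834721932367391,0.25999001602672239,0.68578242063634209
EPG_SOC,m9plus,Q1,0.69652689525388467,0.23839353680088346,0.054105706661679714,0.010973861283552275
EPG_SOC,m9plus,Q2,0.13018278813194678,0.74599983401503567,0.098853839965981072,0.024963537887036459
EPG_SOC,m9plus,Q3,0.027388703670827002,0.12284782019389293,0.72274673075397666,0.12701674538130345
EPG_SOC,m9plus,Q4,0.0058919066064823744,0.039199479631330657,0.19418912232487098,0.7607194914373161
SOC,m1_3,Q1,0.42394391044676472,0.45700914024586065,0.089732508728680299,0.029314440578694256
SOC,m1_3,Q2,0.29541512548598392,0.45244934483960453,0.20812832343275972,0.044007206241651886
SOC,m1_3,Q3,0.056478476652003611,0.29238562750307456,0.43238515956391654,0.21875073628100528
SOC,m1_3,Q4,0.028288070682639721,0.093240535119343673,0.45672845232407239,0.42174294187394429
SOC,m4_8,Q1,0.61740739482767548,0.30536823593337031,0.05905838856625345,0.018165980672700671
SOC,m4_8,Q2,0.16211221232882672,0.64004716306187792,0.15365160083669363,0.044189023772601928
SOC,m4_8,Q3,0.057071701485429761,0.19204109896211885,0.61863891164562379,0.13224828790682755
SOC,m4_8,Q4,0.015556480915770932,0.051875216578579693,0.27925779458684208,0.6533105079188074
SOC,m9plus,Q1,0.71205607662413051,0.22951607815418348,0.049057345205306961,0.0093705000163790738
SOC,m9plus,Q2,0.13830609065224006,0.74639513338803198,0.093146371869165578,0.022152404090562475
SOC,m9plus,Q3,0.030767097984015546,0.12996453080893899,0.72008846726961451,0.1191799039374309
SOC,m9plus,Q4,0.0069280260299569027,0.043408650993462986,0.20251780780034268,0.74714551517623762
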