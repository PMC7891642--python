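species,motu,parent_motu,guilds,A_TEF,A_eDNA,B_TEF,B_eDNA,C_TEF,C_eDNA,D_TEF,D_eDNA,E_TEF,E_eDNA
Abramis brama,Abr_bra,,BEN;OMN;TOL,,3.61,,1.42,2.25,6.34,0.12,14.48,0.07,13.86
Alburnus alburnus,Alb_alb,,PEL;EUR;INS;TOL,12.82,2.02,1.09,1.57,16.53,10.80,57.14,4.15,69.81,5.98
Alburnoides bipunctatus,Alb_bip,,PEL;RHE;INS,41.59,0.81,64.91,5.65,0.09,5.35,1.59,3.67,0.56,1.14
Alosa fallax,Alo_spp,,PEL;RHE,,,,,,,0.01,,0.01,
Ameiurus melas,Ame_mel,,BEN;INS;TOL,,0.41,,,1.49,,,,,
Anguilla anguilla,Ang_ang,,BEN;EUR;TOL,,,,,0.03,,1.11,0.53,1.96,0.78
Barbus barbus,Bar_bab,,BEN;RHE;OMN;POT,5.91,19.14,13.18,23.23,2.54,13.92,2.01,11.08,2.68,10.43
Barbatula barbatula,Bar_bar,,BEN;RHE;INS,0.50,6.07,0.04,4.88,0.08,1.56,4.14,3.92,0.03,3.71
Blicca bjoerkna,Bli_bjo,,BEN;OMN;TOL,1.93,2.10,0.33,2.40,21.37,3.96,6.24,8.07,2.98,3.91
Cottus gobio,Cot_sp,,BEN;EUR;INS,0.56,6.03,0.33,13.15,,3.39,0.08,0.72,,0.60
Cyprinus carpio,Cyp_car,,BEN;OMN;PHY;TOL,0.06,0.17,0.01,0.11,0.36,0.73,0.05,0.84,0.06,0.58
Esox lucius,Eso_luc,,PEL;PHY;POT,0.18,3.62,,2.27,0.01,0.30,0.03,0.22,0.03,0.03
Gasterosteus aculeatus,Gas_acu,,PEL;EUR;INS;PHY;TOL,0.10,0.38,0.04,0.41,0.04,0.02,0.10,0.13,,0.02
Gobio gobio,Gob_gob,,BEN;EUR;OMN,7.86,11.12,1.16,6.83,8.76,2.85,7.25,5.98,1.44,3.90
Gymnocephalus cernuus,Gym_cern,,BEN;INS;TOL,,4.11,,3.21,0.24,10.62,,5.22,,3.31
Lampetra planeri,Lam_spp,,BEN;RHE,,0.04,,0.22,,0.01,,,,
Lepomis gibbosus,Lep_gib,,PEL;INS;TOL,0.04,,,0.38,0.79,1.27,0.03,0.15,0.37,0.17
Perca fluviatilis,Perc_flu,,PEL;TOL,0.04,0.74,0.13,0.38,0.43,1.13,0.12,0.53,0.10,0.42
Phoxinus phoxinus,Pho_pho,,PEL;EUR;INS,0.28,2.11,0.07,2.16,0.11,0.77,0.06,1.65,0.01,0.53
Pseudorasbora parva,Pse_par,,PEL;OMN;TOL,0.08,0.06,0.05,0.10,4.29,0.47,1.87,0.54,1.68,0.42
Rhodeus sericeus,Rho_ser,,PEL,0.02,0.13,0.07,0.14,5.64,0.46,2.16,0.67,3.21,0.76
Rutilus rutilus,Rut_rut,,PEL;OMN;TOL,1.47,6.18,0.34,3.80,8.94,18.22,0.82,19.58,2.17,36.03
Salaria fluviatilis,Sal_flu,,BEN;EUR;INS,,0.75,0.22,1.02,0.17,0.47,0.03,0.42,0.03,1.05
Salmo trutta,Sal_tru,,PEL;EUR;POT,0.12,5.27,0.02,5.44,,0.49,0.08,1.00,0.04,1.54
Sander lucioperca,San_luc,,PEL;TOL,,1.94,,0.39,0.04,3.52,,0.51,0.04,0.50
Scardinius erythrophthalmus,Sca_ery,,PEL;OMN;PHY;TOL,0.02,,,0.14,0.03,,0.04,0.07,0.03,0.10
Silurus glanis,Sil_gla,,BEN;PHY;TOL,0.14,0.74,1.03,0.56,0.24,2.84,0.29,1.92,0.24,1.49
Squalius cephalus,Squ_cep,,PEL;EUR;OMN;POT;TOL,14.11,7.57,15.37,5.96,15.72,4.12,12.29,9.81,9.41,5.71
Thymallus thymallus,Thy_thy,,PEL;RHE;INS;POT,,0.47,,,,,,,,
Tinca tinca,Tin_tin,,BEN;OMN;PHY;TOL,0.04,0.82,0.16,0.25,0.17,,,0.13,,
,Car_spp,,BEN;OMN;PHY;TOL,,,,,,0.32,,0.03,,0.09
Carassius gibelio,,Car_spp,,,,,,1.50,,0.01,,0.07,
Carassius carassius,,Car_spp,,,,0.01,,0.88,,,,,
Carassius auratus,,Car_spp,,,,,,0.08,,,,,
,Leu_spp,,RHE;OMN;POT,,1.78,,1.05,,0.14,,,,
Leuciscus leuciscus,,Leu_spp,,1.95,,0.07,,,,,,,
Leuciscus idus,,Leu_spp,,,,,,0.03,,,,0.01,
,Cypr_1,,RHE;POT,,11.83,,12.89,,5.68,,3.90,,2.87
Parachondrostoma toxostoma,,Cypr_1,,,,,,,,0.01,,,
Chondrostoma nasus,,Cypr_1,,10.15,,1.16,,7.10,,2.06,,2.92,
Telestes souffia,,Cypr_1,,0.02,,0.20,,0.07,,0.27,,0.01,
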